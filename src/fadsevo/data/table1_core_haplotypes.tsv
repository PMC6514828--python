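category	sequence
Ancestral	CCnnnAnCCTCCnnnnnnnnnnnnnnnnnnnnnnnnnn
Derived	nnnGnnnnnGnTGnnCCCTnGTCTAATGCAAGnTAnnC
Native American Ancestral	CCGnTAGCCTCCATCAGTCGACnCGGCnTGnACCGGGn
African Derived	nnnGnnnnAGnTGGTCCCTnGTCTAATGCAAGnTAnnC
Asian Derived	nnnGnnnnnGTTGnnCCCTCGTCTAATGCAAGTTAAAC
Asian Ancestral	CCGGnAnCCTCCnnnnnnnnnnnnnnnGnnnnnnnnnn
European Derived	nnnGnGnnAGnTGnnCCCTnGTCTAATGCAAGnTAnnC
European Ancestral	CCGnnAnCCTCCnnnnnnnnnnnnnnnnnnnnnnnnnn
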