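"""Shared synthetic-input handling for the numbered analysis scripts.

Each script can regenerate its inputs deterministically from a seed, so the
pipeline has no hidden state; `ensure_inputs` materialises the standard
input files under results/data/ once and reuses them afterwards.
"""

from pathlib import Path

from fadsevo.alignment import write_alignment_vcf
from fadsevo.synthetic_data import (
    ClineSimConfig,
    HaplogroupSimConfig,
    PanelSimConfig,
    simulate_cline_table,
    simulate_frequency_panel,
    simulate_haplogroup_alignment,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def ensure_inputs(seed: int = 1) -> dict[str, Path]:
    """Write (or reuse) the alignment, allele-count panel and cline table."""
    DATA.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": DATA / "alignment.vcf",
        "ancestor": DATA / "alignment.ancestor.fa",
        "samples": DATA / "alignment.samples.tsv",
        "mask": DATA / "alignment.mask.tsv",
        "panel_null": DATA / "panel_null.tsv",
        "panel_sweep": DATA / "panel_sweep.tsv",
        "cline": DATA / "cline.tsv",
    }
    if not paths["vcf"].exists():
        aln = simulate_haplogroup_alignment(HaplogroupSimConfig(seed=seed))
        write_alignment_vcf(aln, DATA / "alignment")
    if not paths["panel_null"].exists():
        simulate_frequency_panel(PanelSimConfig(seed=seed)).to_csv(
            paths["panel_null"], sep="\t", index=False
        )
    if not paths["panel_sweep"].exists():
        simulate_frequency_panel(
            PanelSimConfig(seed=seed, selected_site=(4_960, 0.5))
        ).to_csv(paths["panel_sweep"], sep="\t", index=False)
    if not paths["cline"].exists():
        simulate_cline_table(ClineSimConfig(seed=seed)).to_csv(
            paths["cline"], sep="\t", index=False
        )
    return paths
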