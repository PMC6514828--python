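"""Haplogroup classification, proportions, core-haplotype consensus strings
and oppositely fixed sites.

Haplotypes are labelled ancestral or derived solely by their base at the
tag SNP rs174537 (chr11:61,552,680; T ancestral — the allele shared with
nonhuman primates — and G derived).  Per-group proportions can be binned by
population or by local-ancestry label, optionally restricted to samples
with unambiguous (homozygous) ancestry.

A core haplotype summarises a category of haplotypes over the region's
variant positions: a capital base where every haplotype in the category
agrees, a lower-case "n" where the category is variable.  Two core
haplotypes can then be compared for oppositely fixed positions (capital in
both, different base) — candidate functional variants — and "half-fixed"
positions (capital in one, "n" in the other).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment

__all__ = [
    "TagSnpSpec",
    "CoreHaplotype",
    "classify_haplotypes",
    "haplogroup_proportions",
    "core_haplotypes",
    "opposite_fixed_sites",
    "load_table1",
    "TABLE1_TAG_BASE_NUMBER",
]

logger = logging.getLogger(__name__)

# 1-based index of the tag SNP within the published 38-variant core strings
TABLE1_TAG_BASE_NUMBER = 10


@dataclass(frozen=True)
class TagSnpSpec:
    """The haplogroup-defining tag SNP."""

    chrom: str = "chr11"
    pos: int = 61_552_680
    ancestral_allele: str = "T"
    derived_allele: str = "G"
    id: str = "rs174537"

    def __post_init__(self) -> None:
        if self.ancestral_allele == self.derived_allele:
            raise ValueError("ancestral and derived alleles must differ")


def classify_haplotypes(
    alignment: HaplotypeAlignment, tag: TagSnpSpec = TagSnpSpec()
) -> pd.DataFrame:
    """Metadata table with a ``haplogroup`` column set from the tag SNP.

    Haplotypes carrying neither tag allele (including missing bases) are
    'unclassified' and excluded from proportion reports.  Raises ``KeyError``
    naming the position if the tag site is absent.
    """
    try:
        j = alignment.site_index(tag.pos)
    except KeyError:
        raise KeyError(
            f"tag SNP {tag.id} at {tag.chrom}:{tag.pos} absent from alignment"
        ) from None
    base = alignment.haplotypes[:, j]
    haplogroup = np.where(
        base == tag.ancestral_allele,
        "ancestral",
        np.where(base == tag.derived_allele, "derived", "unclassified"),
    )
    n_uncl = int((haplogroup == "unclassified").sum())
    if n_uncl:
        logger.info("%d haplotypes carry neither tag allele; left unclassified", n_uncl)
    out = alignment.metadata.copy()
    out["haplogroup"] = haplogroup
    return out


def haplogroup_proportions(
    labeled: pd.DataFrame,
    group_by: str = "population",
    unambiguous_only: bool = False,
) -> pd.DataFrame:
    """Ancestral/derived counts and fractions per group.

    ``labeled`` needs columns ``sample``, ``haplogroup`` and the ``group_by``
    column (e.g. ``population`` or ``ancestry``).  With
    ``unambiguous_only=True`` only samples whose haplotypes all share one
    ``group_by`` label are kept (homozygous-ancestry restriction).
    Percentages are reported to 2 decimal places alongside raw fractions.
    """
    df = labeled.copy()
    if unambiguous_only:
        n_labels = df.groupby("sample")[group_by].transform("nunique")
        df = df[n_labels == 1]
    df = df[df["haplogroup"].isin(["ancestral", "derived"])]
    rows = []
    for group, sub in df.groupby(group_by, sort=True):
        n = len(sub)
        if n == 0:
            continue
        n_anc = int((sub["haplogroup"] == "ancestral").sum())
        n_der = n - n_anc
        rows.append(
            {
                group_by: group,
                "n_haplotypes": n,
                "n_ancestral": n_anc,
                "n_derived": n_der,
                "frac_ancestral": n_anc / n,
                "frac_derived": n_der / n,
                "pct_ancestral": round(100.0 * n_anc / n, 2),
                "pct_derived": round(100.0 * n_der / n, 2),
            }
        )
    if not rows:
        logger.warning("no classified haplotypes in any group")
    return pd.DataFrame(rows)


@dataclass
class CoreHaplotype:
    """Per-category consensus over variant positions: capitals where fixed,
    'n' where variable."""

    category: str
    sequence: str
    positions: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.sequence)

    def fixed_mask(self) -> np.ndarray:
        return np.array([c != "n" for c in self.sequence])


def core_haplotypes(
    alignment: HaplotypeAlignment,
    categories: pd.Series | np.ndarray | list,
    missing: str = "N",
    fixed_threshold: float = 1.0,
) -> dict[str, CoreHaplotype]:
    """Core-haplotype string per category over the alignment's variant
    positions (sites polymorphic among the supplied haplotypes, ordered by
    coordinate).

    A position is a capital base when at least ``fixed_threshold`` (default
    1.0, i.e. all) of the category's non-missing bases agree; otherwise
    'n'.  Positions missing in more than half of a category's haplotypes
    are emitted as 'n' with a warning.  A category with zero haplotypes is
    an error.
    """
    labels = pd.Series(list(categories), dtype=object)
    if len(labels) != alignment.n_haplotypes:
        raise ValueError("need one category label per haplotype")
    var_mask = alignment.polymorphic_mask()
    positions = alignment.positions[var_mask]
    out: dict[str, CoreHaplotype] = {}
    for cat in labels.dropna().unique():  # keeps input order
        rows = alignment.haplotypes[(labels == cat).to_numpy()][:, var_mask]
        if rows.shape[0] == 0:
            raise ValueError(f"category {cat!r} has no haplotypes")
        chars = []
        for j in range(rows.shape[1]):
            col = rows[:, j]
            ok = col != missing
            if ok.sum() < rows.shape[0] / 2.0:
                logger.warning(
                    "category %s: position %d missing in >50%% of haplotypes", cat, positions[j]
                )
                chars.append("n")
                continue
            vals, counts = np.unique(col[ok], return_counts=True)
            top = counts.argmax()
            if counts[top] / ok.sum() >= fixed_threshold:
                chars.append(str(vals[top]).upper())
            else:
                chars.append("n")
        out[str(cat)] = CoreHaplotype(str(cat), "".join(chars), positions.copy())
    return out


def opposite_fixed_sites(
    core_a: CoreHaplotype | str,
    core_b: CoreHaplotype | str,
    exclude: int | None = None,
) -> dict[str, list[int]]:
    """Positions fixed in opposite directions between two core haplotypes.

    Returns 1-based base numbers along the strings:

    * ``opposite_fixed`` — capital in both and different (candidate causal
      variants), optionally excluding the tag-SNP base number;
    * ``half_fixed`` — capital in exactly one of the two (less likely
      candidates).
    """
    seq_a = core_a.sequence if isinstance(core_a, CoreHaplotype) else core_a
    seq_b = core_b.sequence if isinstance(core_b, CoreHaplotype) else core_b
    if len(seq_a) != len(seq_b):
        raise ValueError("core haplotype strings differ in length")
    opposite, half = [], []
    for i, (a, b) in enumerate(zip(seq_a, seq_b), start=1):
        if exclude is not None and i == exclude:
            continue
        a_fixed, b_fixed = a != "n", b != "n"
        if a_fixed and b_fixed and a != b:
            opposite.append(i)
        elif a_fixed != b_fixed:
            half.append(i)
    return {"opposite_fixed": opposite, "half_fixed": half}


def load_table1() -> pd.DataFrame:
    """The packaged published core-haplotype strings (one row per category,
    38 variant positions each; base number 10 is the tag SNP)."""
    ref = importlib.resources.files("fadsevo") / "data" / "table1_core_haplotypes.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
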