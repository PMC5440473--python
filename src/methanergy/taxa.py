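"""Methane-cycler guild screen over classified 16S taxon-abundance tables.

Starting from an already-classified table (semicolon-ranked lineage strings
by sample counts, mothur shared/cons.taxonomy flavor), lineages are assigned
to four guilds — aerobic methanotrophic bacteria, the NO-dismutating NC10
clade, methanogenic archaea (by order), and anaerobic methanotrophic archaea
(ANME clades) — and per-sample relative abundances are computed against the
domain's total read count (archaeal fractions over archaeal reads, bacterial
over bacterial, matching separately amplified datasets).

Matching is exact-token per rank after whitespace/quote/confidence
normalization: genus names match at the genus rank, order names at the order
rank, ANME clade labels at any rank. Lineages carrying an ANME label or
Methanoperedens (the ANME-2d genus, which nests inside the otherwise
methanogenic order Methanosarcinales) are overridden into the ANME guild.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyTable",
    "GuildLists",
    "ScreenResult",
    "default_guild_lists",
    "parse_lineage",
    "classify_lineage",
    "screen_methane_cyclers",
    "guild_summary",
    "read_taxonomy_table",
    "write_taxonomy_table",
]

#: 0-based lineage rank positions (domain;phylum;class;order;family;genus)
ORDER_RANK = 3
GENUS_RANK = 5

GUILDS = ("methanotroph_bacteria", "NC10", "methanogen", "ANME")

_CONFIDENCE = re.compile(r"\(\d+(\.\d+)?\)$")


@dataclass
class TaxonomyTable:
    """Lineage strings x per-sample nonnegative integer counts."""

    lineages: list[str]
    counts: pd.DataFrame  # rows align with lineages; columns are sample ids

    def __post_init__(self):
        if len(self.lineages) != len(self.counts):
            raise ValueError("lineages and counts row count differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GuildLists:
    """The screened taxon lists.

    ``methanotroph_genera`` retains the original (misspelled)
    "Methyothermus" alongside the standard "Methylothermus" so that tables
    transcribed either way are matched. ``special_cases`` maps a lineage
    token to the guild that overrides rank-based assignment (Methanoperedens
    -> ANME).
    """

    methanotroph_genera: frozenset[str]
    methanogen_orders: frozenset[str]
    anme_labels: frozenset[str]
    nc10_labels: frozenset[str]
    special_cases: dict[str, str] = field(default_factory=dict)


def default_guild_lists() -> GuildLists:
    return GuildLists(
        methanotroph_genera=frozenset({
            # Methylococcaceae (Gammaproteobacteria)
            "Methylococcus", "Methylocaldum", "Methylohalobius",
            "Methyothermus", "Methylothermus", "Methylobacter",
            "Methylomicrobium", "Methylomonas", "Methylosarcina",
            "Methylosoma", "Methylosphaera", "Crenothrix", "Clonothrix",
            # Methylocystaceae / Beijerinckiaceae (Alphaproteobacteria)
            "Methylocystis", "Methylosinus", "Methylocella", "Methylocapsa",
            # Verrucomicrobia
            "Methylacidiphilum",
        }),
        methanogen_orders=frozenset({
            "Methanopyrales", "Methanococcales", "Methanobacteriales",
            "Methanomicrobiales", "Methanocellales", "Methanoplasmatales",
            "Methanosarcinales",
        }),
        anme_labels=frozenset({
            "ANME-1", "ANME-1a", "ANME-1b", "ANME-2", "ANME-2a", "ANME-2b",
            "ANME-2c", "ANME-2d", "ANME-3",
        }),
        nc10_labels=frozenset({"Methylomirabilis", "NC10"}),
        special_cases={"Methanoperedens": "ANME"},
    )


def parse_lineage(lineage: str) -> list[str]:
    """Split a semicolon-ranked lineage into normalized rank tokens."""
    tokens = []
    for raw in lineage.split(";"):
        tok = _CONFIDENCE.sub("", raw.strip()).strip()
        tok = tok.strip('"').strip()
        for prefix in ("Candidatus ", "Ca. ", "Ca_", "Candidatus_"):
            if tok.startswith(prefix):
                tok = tok[len(prefix):]
        if tok:
            tokens.append(tok)
    return tokens


def _eq(a: str, b: str) -> bool:
    return a.casefold() == b.casefold()


def classify_lineage(lineage: str, g: GuildLists) -> Optional[str]:
    """Guild of one lineage, or None. Overrides win over rank matches."""
    ranks = parse_lineage(lineage)
    for token in ranks:
        for pattern, guild in g.special_cases.items():
            if _eq(token, pattern):
                return guild
    for token in ranks:
        if any(_eq(token, lbl) for lbl in g.anme_labels):
            return "ANME"
    if len(ranks) > ORDER_RANK:
        tok = ranks[ORDER_RANK]
        if any(_eq(tok, o) for o in g.methanogen_orders):
            return "methanogen"
    for token in ranks:
        if any(_eq(token, lbl) for lbl in g.nc10_labels):
            return "NC10"
    if len(ranks) > GENUS_RANK:
        tok = ranks[GENUS_RANK]
        if any(_eq(tok, gen) for gen in g.methanotroph_genera):
            return "methanotroph_bacteria"
    return None


@dataclass
class ScreenResult:
    """Per-sample guild fractions (of the domain's total counts) and the
    matched-lineage inventory. Fractions are NaN for samples with zero
    counts in the domain."""

    domain: str
    fractions: pd.DataFrame  # index: sample ids; columns: GUILDS
    matched_lineages: dict[str, list[str]]
    domain_totals: pd.Series

    def combined_methane_cycler_fraction(self) -> pd.Series:
        """methanogen + ANME fraction per sample (archaeal screen)."""
        return self.fractions["methanogen"] + self.fractions["ANME"]


def screen_methane_cyclers(
    t: TaxonomyTable,
    g: GuildLists | None = None,
    domain_label: str = "Archaea",
) -> ScreenResult:
    """Guild relative abundances per sample within one domain."""
    g = g or default_guild_lists()
    in_domain = np.array([
        bool(parse_lineage(lin)) and _eq(parse_lineage(lin)[0], domain_label)
        for lin in t.lineages
    ])
    guild_of = [
        classify_lineage(lin, g) if keep else None
        for lin, keep in zip(t.lineages, in_domain)
    ]

    counts = t.counts.to_numpy(dtype=float)
    domain_totals = counts[in_domain].sum(axis=0) if in_domain.any() else np.zeros(counts.shape[1])
    frac = pd.DataFrame(index=t.sample_ids, columns=list(GUILDS), dtype=float)
    matched: dict[str, list[str]] = {guild: [] for guild in GUILDS}
    for guild in GUILDS:
        mask = np.array([gl == guild for gl in guild_of])
        guild_counts = counts[mask].sum(axis=0) if mask.any() else np.zeros(counts.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            frac[guild] = np.where(domain_totals > 0,
                                   guild_counts / np.maximum(domain_totals, 1e-300),
                                   np.nan)
        matched[guild] = [lin for lin, m in zip(t.lineages, mask) if m]
    return ScreenResult(
        domain=domain_label,
        fractions=frac,
        matched_lineages=matched,
        domain_totals=pd.Series(domain_totals, index=t.sample_ids),
    )


def guild_summary(
    result: ScreenResult, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Min/max of the combined methanogen + ANME fraction per sample group."""
    combined = result.combined_methane_cycler_fraction()
    rows = []
    for group, sample_ids in groups.items():
        if not sample_ids:
            raise ValueError(f"group {group!r} is empty")
        vals = combined.loc[list(sample_ids)]
        rows.append({"group": group, "n_samples": len(sample_ids),
                     "min_fraction": float(vals.min()),
                     "max_fraction": float(vals.max())})
    return pd.DataFrame(rows).set_index("group")


def read_taxonomy_table(path: str | Path) -> TaxonomyTable:
    """TSV with a 'lineage' column and one integer column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"lineage": str})
    if "lineage" not in df.columns:
        raise ValueError("taxonomy table must have a 'lineage' column")
    sample_cols = [c for c in df.columns if c != "lineage"]
    if not sample_cols:
        raise ValueError("taxonomy table has no sample columns")
    counts = df[sample_cols].astype(int)
    return TaxonomyTable(lineages=df["lineage"].tolist(), counts=counts)


def write_taxonomy_table(t: TaxonomyTable, path: str | Path) -> None:
    out = t.counts.copy()
    out.insert(0, "lineage", t.lineages)
    out.to_csv(path, sep="\t", index=False)
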