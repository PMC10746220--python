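"""Screening, quality tiering, dereplication and taxonomy-level rules for
candidate genome bins.

A candidate bin is called a putative eukaryotic MAG when it is longer than
2.5 Mbp and more than 90% of its length sits on contigs domain-called
eukaryotic (contigs called 'unknown' count toward total length only).
Eukaryotic bins are then tiered by BUSCO completeness (>30% highly
complete, >10% reported), prokaryotic bins by CheckM completeness and
contamination (HQ: >90% / <5%; MQ: 75–90% / <10%).  Redundant genomes are
collapsed at >=99% average nucleotide identity by single-linkage
clustering, and a cluster representative is chosen by a dRep-style score
S = completeness - 5*contamination + 0.5*log10(N50).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_MIN_LENGTH_BP = 2_500_000
DEFAULT_MIN_EUK_FRACTION = 0.90
DEFAULT_ANI_THRESHOLD = 99.0


class QualityTier(enum.Enum):
    EUK_CANDIDATE = "EUK_CANDIDATE"
    EUK_REPORTED = "EUK_REPORTED"
    EUK_HIGH = "EUK_HIGH"
    PROK_HQ = "PROK_HQ"
    PROK_MQ = "PROK_MQ"
    DISCARD = "DISCARD"


@dataclass
class BinRecord:
    """One genome bin with its contigs, lengths, domain calls and quality metrics."""

    bin_id: str
    contig_ids: list[str] = field(default_factory=list)
    total_length: int = 0
    euk_length: int = 0
    busco_completeness: float | None = None
    busco_duplication: float | None = None
    checkm_completeness: float | None = None
    checkm_contamination: float | None = None
    n50: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.euk_length <= self.total_length):
            raise ValueError(
                f"{self.bin_id}: euk_length ({self.euk_length}) must lie in "
                f"[0, total_length={self.total_length}]"
            )
        for name in ("busco_completeness", "busco_duplication",
                     "checkm_completeness", "checkm_contamination"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{self.bin_id}: {name}={v} outside [0, 100]")


@dataclass
class ScreenResult:
    bin_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    euk_fraction: float = float("nan")


def screen_eukaryotic_bin(
    bin: BinRecord,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    min_euk_fraction: float = DEFAULT_MIN_EUK_FRACTION,
) -> ScreenResult:
    """Putative-eukaryote screen: total length strictly greater than
    ``min_length_bp`` AND eukaryotic fraction by length strictly greater
    than ``min_euk_fraction``.  Failures list every violated criterion.
    """
    if bin.total_length == 0:
        raise ValueError(f"{bin.bin_id}: total_length is zero")
    frac = bin.euk_length / bin.total_length
    reasons = []
    if not bin.total_length > min_length_bp:
        reasons.append(
            f"total_length {bin.total_length} <= minimum {min_length_bp}"
        )
    if not frac > min_euk_fraction:
        reasons.append(
            f"eukaryotic fraction {frac:.4f} <= minimum {min_euk_fraction}"
        )
    return ScreenResult(bin.bin_id, passed=not reasons, reasons=reasons, euk_fraction=frac)


def tier_eukaryotic_completeness(busco_completeness: float) -> QualityTier:
    """BUSCO-based eukaryote tier: >30% highly complete, >10% reported,
    otherwise candidate only (strict inequalities)."""
    if not 0 <= busco_completeness <= 100:
        raise ValueError(f"BUSCO completeness {busco_completeness} outside [0, 100]")
    if busco_completeness > 30:
        return QualityTier.EUK_HIGH
    if busco_completeness > 10:
        return QualityTier.EUK_REPORTED
    return QualityTier.EUK_CANDIDATE


def tier_prokaryotic_quality(completeness: float, contamination: float) -> QualityTier:
    """CheckM-based prokaryote tier: HQ (>90 complete, <5 contaminated),
    MQ (>=75 complete, <10 contaminated), else discard."""
    for v, name in ((completeness, "completeness"), (contamination, "contamination")):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} {v} outside [0, 100]")
    if completeness > 90 and contamination < 5:
        return QualityTier.PROK_HQ
    if completeness >= 75 and contamination < 10:
        return QualityTier.PROK_MQ
    return QualityTier.DISCARD


# ---------------------------------------------------------------------------
# ANI dereplication
# ---------------------------------------------------------------------------

@dataclass
class ANIMatrix:
    """Symmetric pairwise average-nucleotide-identity matrix (percent)."""

    genome_ids: list[str]
    ani: np.ndarray

    def __post_init__(self) -> None:
        self.ani = np.asarray(self.ani, dtype=float)
        n = len(self.genome_ids)
        if self.ani.shape != (n, n):
            raise ValueError("ANI matrix shape does not match genome_ids")
        if not np.allclose(self.ani, self.ani.T, atol=1e-9):
            raise ValueError("ANI matrix is not symmetric")
        if not np.allclose(np.diag(self.ani), 100.0):
            raise ValueError("ANI matrix diagonal must be 100")
        self._index = {g: i for i, g in enumerate(self.genome_ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.ani[self._index[a], self._index[b]])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ANIMatrix":
        if list(df.index) != list(df.columns):
            df = df.loc[:, df.index]
        return cls(list(df.index), df.values)


def drep_score(
    completeness: float,
    contamination: float,
    n50: float,
    w_completeness: float = 1.0,
    w_contamination: float = 5.0,
    w_n50: float = 0.5,
) -> float:
    """dRep-style representative score
    S = completeness - 5*contamination + 0.5*log10(N50)."""
    if n50 <= 0:
        raise ValueError(f"N50 must be positive, got {n50}")
    return (
        w_completeness * completeness
        - w_contamination * contamination
        + w_n50 * math.log10(n50)
    )


@dataclass
class DereplicationResult:
    clusters: list[list[str]]
    representatives: list[str]

    def cluster_of(self, genome_id: str) -> int:
        for i, members in enumerate(self.clusters):
            if genome_id in members:
                return i
        raise KeyError(genome_id)


def dereplicate(
    genomes: Sequence[BinRecord],
    ani: ANIMatrix,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
) -> DereplicationResult:
    """Single-linkage clustering of genomes at ANI >= threshold, with one
    representative per cluster maximizing the dRep-style score; ties are
    broken by larger total length then lexicographic bin id.

    Cluster ordering is canonical (by smallest member id), so the result
    is invariant to the input order of ``genomes``.
    """
    by_id = {g.bin_id: g for g in genomes}
    missing = [g.bin_id for g in genomes if g.bin_id not in ani._index]
    if missing:
        raise KeyError(f"genomes missing from ANI matrix: {missing}")
    ids = sorted(by_id)
    idx = [ani._index[g] for g in ids]
    sub = ani.ani[np.ix_(idx, idx)]
    adj = csr_matrix(sub >= ani_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for g, lab in zip(ids, labels):
        clusters[lab].append(g)
    clusters = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
    reps = []
    for members in clusters:
        def key(g: str):
            rec = by_id[g]
            s = drep_score(
                rec.checkm_completeness if rec.checkm_completeness is not None
                else (rec.busco_completeness or 0.0),
                rec.checkm_contamination or 0.0,
                rec.n50 or 1,
            )
            # maximize score, then total_length; bin_id ascending as final tie-break
            return (-s, -rec.total_length, g)
        reps.append(min(members, key=key))
    return DereplicationResult(clusters, reps)


# ---------------------------------------------------------------------------
# Taxonomy-level assignment
# ---------------------------------------------------------------------------

# (lower bound exclusive, level); the deepest level whose lower bound is
# strictly exceeded wins, so shared boundary values fall to the shallower level.
_LEVEL_CUTOFFS = (
    (95.0, "species"),
    (80.0, "genus"),
    (65.0, "family"),
    (50.0, "order"),
    (30.0, "class"),
)


def assign_taxonomic_level(percent_identity: float) -> str | None:
    """Map a best-hit percent identity to the deepest defensible taxonomic
    level: species >95; genus (80,95]; family (65,80]; order (50,65];
    class (30,50]; None at or below 30."""
    if not 0 <= percent_identity <= 100:
        raise ValueError(f"percent identity {percent_identity} outside [0, 100]")
    for lower, level in _LEVEL_CUTOFFS:
        if percent_identity > lower:
            return level
    return None


@dataclass
class TaxonReportNode:
    """Node of a taxonomy report tree: cumulative percent of mappings at or
    below this node, monotone non-increasing from root to leaves."""

    taxon_id: int
    name: str
    rank: str
    percent_mapped: float
    children: list["TaxonReportNode"] = field(default_factory=list)

    def validate_monotone(self) -> None:
        for child in self.children:
            if child.percent_mapped > self.percent_mapped + 1e-9:
                raise ValueError(
                    f"child {child.name!r} ({child.percent_mapped}%) exceeds "
                    f"parent {self.name!r} ({self.percent_mapped}%)"
                )
            child.validate_monotone()


def select_taxon_from_report(
    root: TaxonReportNode,
    min_percent: float = 8.0,
    first_exceeding: bool = False,
) -> tuple[TaxonReportNode, list[str]]:
    """Descend a taxonomy report, at each step following the child with the
    greatest percent of mappings while that percent exceeds ``min_percent``,
    stopping at a strain-rank node or when no child qualifies; the last node
    visited is the assignment.

    ``first_exceeding=True`` switches to the alternative reading in which
    the walk stops at the first node *below the root* whose percent exceeds
    the threshold.  Returns (node, warnings).
    """
    warnings: list[str] = []
    root.validate_monotone()
    if root.percent_mapped <= min_percent:
        warnings.append(
            f"root mapping percent {root.percent_mapped} <= threshold {min_percent}; "
            "returning root"
        )
        return root, warnings
    node = root
    while node.rank != "strain":
        qualifying = [c for c in node.children if c.percent_mapped > min_percent]
        if not qualifying:
            break
        node = max(qualifying, key=lambda c: (c.percent_mapped, c.name))
        if first_exceeding:
            break
    return node, warnings


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def build_bin_records(
    membership: pd.DataFrame,
    domains: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[BinRecord]:
    """Assemble :class:`BinRecord` objects from a bin-membership table
    (bin_id, contig_id), a per-contig domain-call table (contig_id,
    domain in {euk, prok, unknown}, optionally length), and an optional
    quality table indexed by bin_id.

    Contig lengths come from ``contig_lengths`` (e.g. a FASTA read) or a
    ``length`` column of the domain table.
    """
    dom = domains.set_index("contig_id") if "contig_id" in domains.columns else domains
    if contig_lengths is None:
        if "length" not in dom.columns:
            raise ValueError("contig lengths required: pass contig_lengths or a 'length' column")
        contig_lengths = dom["length"].astype(int).to_dict()
    qual = None
    if quality is not None:
        qual = quality.set_index("bin_id") if "bin_id" in quality.columns else quality
    records = []
    for bin_id, group in membership.groupby("bin_id", sort=True):
        contigs = list(group["contig_id"])
        unknown = [c for c in contigs if c not in contig_lengths]
        if unknown:
            raise KeyError(f"bin {bin_id}: contigs without length: {unknown[:5]}")
        total = sum(contig_lengths[c] for c in contigs)
        euk = sum(
            contig_lengths[c]
            for c in contigs
            if c in dom.index and str(dom.loc[c, "domain"]) == "euk"
        )
        kwargs = {}
        if qual is not None and bin_id in qual.index:
            row = qual.loc[bin_id]
            for col, attr in (
                ("busco_completeness", "busco_completeness"),
                ("busco_duplication", "busco_duplication"),
                ("completeness", "checkm_completeness"),
                ("contamination", "checkm_contamination"),
            ):
                if col in row.index and pd.notna(row[col]):
                    kwargs[attr] = float(row[col])
            if "n50" in row.index and pd.notna(row["n50"]):
                kwargs["n50"] = int(row["n50"])
        records.append(
            BinRecord(
                bin_id=str(bin_id),
                contig_ids=contigs,
                total_length=total,
                euk_length=euk,
                **kwargs,
            )
        )
    return records
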