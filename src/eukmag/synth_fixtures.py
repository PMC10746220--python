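"""Seed-deterministic synthetic inputs with the statistical structure each
pipeline stage assumes, so the whole toolkit is exercisable without any
external download.

Three generators are provided:

* a labelled reference panel of KO presence/absence profiles in which a
  subset of KOs is informative for trophic mode (elevated occurrence
  within one mode, depressed elsewhere) against a uniform background —
  the shape of a curated reference transcriptome panel;
* a MAG x sample abundance matrix with planted co-occurring communities
  (members share a lognormal latent abundance trajectory plus independent
  noise) and independent background MAGs, together with environmental
  covariates monotonically linked to chosen community latents;
* toy genome bins (contig FASTA + per-contig domain calls + quality
  table) straddling the eukaryote screening thresholds, including
  exact-boundary cases.

All generators return plain in-memory objects (and can write the same
TSV/FASTA dialects the pipeline consumes); identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .io_formats import SequenceCollection, write_fasta
from .trophic import MODES, KOProfile

DEFAULT_PANEL = dict(
    n_refs_per_mode=300,
    n_kos=2000,
    n_informative=300,
    occ_in_mode=0.9,
    occ_out_mode=0.1,
    background_occ=0.5,
)


@dataclass(frozen=True)
class PanelSpec:
    """Shape of the synthetic labelled reference panel."""

    n_refs_per_mode: int = 300
    n_kos: int = 2000
    n_informative: int = 300
    occ_in_mode: float = 0.9
    occ_out_mode: float = 0.1
    background_occ: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.occ_in_mode, self.occ_out_mode, self.background_occ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_informative > self.n_kos:
            raise ValueError("n_informative exceeds n_kos")


@dataclass
class TrophicPanel:
    profiles: list[KOProfile]
    informative_kos: dict[str, list[str]]  # mode -> its informative KOs
    spec: PanelSpec

    @property
    def all_informative(self) -> list[str]:
        return sorted(k for kos in self.informative_kos.values() for k in kos)


def make_trophic_panel(spec: PanelSpec) -> TrophicPanel:
    """Draw a labelled KO presence/absence panel.

    The ``n_informative`` KOs are split evenly across the three modes;
    each is present with probability ``occ_in_mode`` in references of its
    own mode and ``occ_out_mode`` elsewhere.  The remaining KOs are
    background, present with ``background_occ`` everywhere.  A spec in
    which informative and background occurrence coincide generates no
    signal and earns a warning.
    """
    import logging

    if spec.n_informative > 0 and spec.occ_in_mode == spec.occ_out_mode:
        logging.getLogger(__name__).warning(
            "degenerate panel spec: occ_in_mode == occ_out_mode; informative "
            "KOs carry no signal"
        )
    rng = np.random.default_rng(spec.seed)
    kos = [f"K{j:05d}" for j in range(1, spec.n_kos + 1)]
    per_mode = spec.n_informative // len(MODES)
    informative: dict[str, list[str]] = {}
    cursor = 0
    for mode in MODES:
        take = per_mode if mode != MODES[-1] else spec.n_informative - cursor
        informative[mode] = kos[cursor:cursor + take]
        cursor += take
    background = kos[spec.n_informative:]
    profiles: list[KOProfile] = []
    for mode in MODES:
        for i in range(spec.n_refs_per_mode):
            present: set[str] = set()
            for owner in MODES:
                block = informative[owner]
                p = spec.occ_in_mode if owner == mode else spec.occ_out_mode
                mask = rng.random(len(block)) < p
                present.update(np.asarray(block)[mask])
            mask = rng.random(len(background)) < spec.background_occ
            present.update(np.asarray(background)[mask])
            profiles.append(KOProfile(f"{mode}_{i:04d}", present, label=mode))
    return TrophicPanel(profiles, informative, spec)


# ---------------------------------------------------------------------------
# Abundance matrices with planted communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    n_members: int = 8
    noise_sd: float = 0.2
    latent_sd: float = 1.0


@dataclass(frozen=True)
class AbundanceSimSpec:
    """Shape of the synthetic station x MAG abundance matrix."""

    n_samples: int = 60
    communities: tuple[CommunitySpec, ...] = (CommunitySpec(), CommunitySpec())
    n_background_mags: int = 4
    env_linked: tuple[int, ...] = (0,)  # community indices with a linked covariate
    background_prok_fraction: float = 0.5
    seed: int = 0


@dataclass
class AbundanceSim:
    cpm: AbundanceMatrix
    truth: dict[str, int]          # planted community per member MAG
    domains: dict[str, str]        # mag -> eukaryote / prokaryote
    env: pd.DataFrame              # sample x covariate
    spec: AbundanceSimSpec


def make_abundance_matrix(spec: AbundanceSimSpec) -> AbundanceSim:
    """Simulate a CPM-like abundance matrix with planted communities.

    Members of a community share one lognormal latent trajectory across
    samples and differ by independent lognormal noise (sd ``noise_sd`` in
    log space), so within-community Spearman correlations are high;
    background MAGs are fully independent.  Each community listed in
    ``env_linked`` gets an environmental covariate that is a noisy
    monotone transform of its latent.  Columns are renormalized to sum to
    1e6 so the output is a valid CPM matrix.
    """
    if spec.n_samples < 10:
        import logging

        logging.getLogger(__name__).warning(
            "n_samples=%d < 10: correlation estimates will be unstable",
            spec.n_samples,
        )
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{j:03d}" for j in range(spec.n_samples)]
    rows: dict[str, np.ndarray] = {}
    truth: dict[str, int] = {}
    domains: dict[str, str] = {}
    env_cols: dict[str, np.ndarray] = {}
    for ci, comm in enumerate(spec.communities):
        latent = rng.normal(0.0, comm.latent_sd, size=spec.n_samples)
        for mi in range(comm.n_members):
            mag = f"C{ci}_MAG{mi:02d}"
            noise = rng.normal(0.0, comm.noise_sd, size=spec.n_samples)
            rows[mag] = np.exp(latent + noise)
            truth[mag] = ci
            domains[mag] = "eukaryote"
        if ci in spec.env_linked:
            env_cols[f"env_comm{ci}"] = np.exp(
                latent + rng.normal(0.0, comm.noise_sd, size=spec.n_samples)
            )
    n_prok = int(round(spec.n_background_mags * spec.background_prok_fraction))
    for bi in range(spec.n_background_mags):
        mag = f"BG_MAG{bi:02d}"
        rows[mag] = np.exp(rng.normal(0.0, 1.0, size=spec.n_samples))
        domains[mag] = "prokaryote" if bi < n_prok else "eukaryote"
    env_cols["env_noise"] = rng.normal(0.0, 1.0, size=spec.n_samples)
    values = pd.DataFrame(rows, index=samples).T
    values = values / values.sum(axis=0) * 1_000_000.0
    cpm = AbundanceMatrix(values, "CPM")
    env = pd.DataFrame(env_cols, index=samples)
    return AbundanceSim(cpm, truth, domains, env, spec)


# ---------------------------------------------------------------------------
# Toy genome bins
# ---------------------------------------------------------------------------

@dataclass
class ToyBins:
    sequences: SequenceCollection
    membership: pd.DataFrame   # bin_id, contig_id
    domains: pd.DataFrame      # contig_id, domain, length
    quality: pd.DataFrame      # bin_id, completeness, contamination, n50

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "contigs.fasta")
        self.membership.to_csv(outdir / "bins.tsv", sep="\t", index=False)
        self.domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
        self.quality.to_csv(outdir / "quality.tsv", sep="\t", index=False)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def make_toy_bins(
    n_bins: int = 6,
    seed: int = 0,
    length_threshold: int = 2_500_000,
    euk_fraction_threshold: float = 0.90,
    contigs_per_bin: int = 4,
) -> ToyBins:
    """Generate toy bins whose sizes and eukaryotic fractions straddle the
    screening thresholds.

    The first three bins are fixed boundary cases: one exactly at the
    length threshold (fails the strict > test), one just above it with
    eukaryotic fraction exactly at the fraction threshold (also fails),
    and one clearly passing both.  Remaining bins are random around the
    thresholds.  Emitted FASTA lengths always equal the table lengths.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    seq_records: list[tuple[str, str, int]] = []
    mem_rows, dom_rows, qual_rows = [], [], []

    def add_bin(bin_id: str, total: int, euk_frac: float) -> None:
        # split total into contigs; first contigs are eukaryotic up to euk_frac
        base = total // contigs_per_bin
        lengths = [base] * (contigs_per_bin - 1)
        lengths.append(total - sum(lengths))
        euk_target = int(round(total * euk_frac))
        acc = 0
        for ci, ln in enumerate(lengths):
            contig = f"{bin_id}_c{ci}"
            # domain: eukaryotic while cumulative euk length fits the target
            if acc + ln <= euk_target:
                domain = "euk"
                acc += ln
            elif acc < euk_target:
                # split the straddling contig so fraction is hit exactly
                head = euk_target - acc
                seq = _random_seq(rng, head)
                seq_records.append((f"{contig}e", seq, head))
                mem_rows.append((bin_id, f"{contig}e"))
                dom_rows.append((f"{contig}e", "euk", head))
                acc = euk_target
                ln = ln - head
                if ln == 0:
                    continue
                domain = rng.choice(["prok", "unknown"])
            else:
                domain = rng.choice(["prok", "unknown"])
            seq = _random_seq(rng, ln)
            seq_records.append((contig, seq, ln))
            mem_rows.append((bin_id, contig))
            dom_rows.append((contig, domain, ln))
        qual_rows.append(
            (
                bin_id,
                float(np.round(rng.uniform(40, 99), 2)),
                float(np.round(rng.uniform(0, 12), 2)),
                int(max(lengths)),
            )
        )

    add_bin("bin000_at_length", length_threshold, 0.99)
    if n_bins > 1:
        add_bin("bin001_at_fraction", length_threshold + 1000, euk_fraction_threshold)
    if n_bins > 2:
        add_bin("bin002_pass", int(length_threshold * 1.2), 0.96)
    for i in range(3, n_bins):
        total = int(length_threshold * rng.uniform(0.7, 1.5))
        frac = float(rng.uniform(0.6, 1.0))
        add_bin(f"bin{i:03d}", total, frac)

    seqs = SequenceCollection(seq_records)
    membership = pd.DataFrame(mem_rows, columns=["bin_id", "contig_id"])
    domains = pd.DataFrame(dom_rows, columns=["contig_id", "domain", "length"])
    quality = pd.DataFrame(
        qual_rows, columns=["bin_id", "completeness", "contamination", "n50"]
    )
    return ToyBins(seqs, membership, domains, quality)
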