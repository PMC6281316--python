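"""Synthetic dikaryon / homokaryon data generator with known ground truth.

The generator emulates the statistical structure of single-nucleus sequencing
of an arbuscular mycorrhizal fungus:

* two co-existing nucleotypes at ~0.1% divergence, mixed 50:50 in the bulk
  assembly reads (dikaryon) or a single nucleotype (homokaryon);
* per-nucleus genomes covered only partially (whole-genome amplification
  drops out whole loci, modelled as contiguous covered blocks);
* modest per-position read depth with sequencing/WGA substitution errors;
* exact duplicated reference segments, to exercise the flanking-sequence
  single-copy filter;
* optional recombination tracts that exchange genotype blocks between the
  two nucleotypes in individual nuclei;
* a small number of "collapsed duplicate" artifact positions — a hidden
  paralog absent from the assembly, showing ~50% alternate allele frequency
  in the bulk and amplification-skewed support in single nuclei.  This is
  the channel through which a homokaryon retains a handful of
  stringent-tier SNPs, as real homokaryotic isolates do.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` sub-streams, so outputs are byte-identical
for identical configs, and per-nucleus coverage masks are *nested* as
``nucleus_coverage_fraction`` grows (same seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import intervals as iv
from .io import (
    CoverageProfile,
    Reference,
    SiteObservation,
    write_bed,
    write_coverage,
    write_reference,
    write_vcf,
)

_BASES = np.array(list("ACGT"))

MAT_LABELS = ("MAT-1", "MAT-5")

# SeedSequence spawn keys, one per independent randomness consumer
_SK_REFERENCE = 0
_SK_NUCLEOTYPES = 1
_SK_MASKS = 2
_SK_NUCLEUS_OBS = 3
_SK_BULK = 4


def default_scaffold_lengths(total_bp: int, n_scaffolds: int) -> list[int]:
    """Deterministic descending scaffold lengths with ~10x max/min spread."""
    if n_scaffolds < 1:
        raise ValueError("need at least one scaffold")
    if n_scaffolds == 1:
        return [total_bp]
    r = 10.0 ** (-1.0 / (n_scaffolds - 1))
    weights = r ** np.arange(n_scaffolds)
    lengths = np.floor(total_bp * weights / weights.sum()).astype(int)
    lengths[0] += total_bp - int(lengths.sum())
    return sorted((int(x) for x in lengths), reverse=True)


@dataclass
class SimConfig:
    """Study conditions for one simulated isolate.

    Defaults follow the regime of the single-nucleus sequencing study being
    emulated: ~0.1% nucleotype divergence, a 50:50 dikaryotic bulk mixture,
    16 nuclei (8 per mating type), ~40% per-nucleus reference coverage with
    ~15x position depth, and a bulk assembly depth of ~50x, at a desk-scale
    1 Mb / 20-scaffold genome.
    """

    seed: int = 0
    n_scaffolds: int = 20
    genome_size: int = 1_000_000
    scaffold_lengths: list[int] | None = None
    divergence: float = 0.001
    dup_fraction: float = 0.02
    dup_segment_length: int = 2000
    n_nuclei_per_mat: int = 8
    recomb_tracts: list[tuple[int, str, int, int]] = field(default_factory=list)
    bulk_mean_depth: float = 50.0
    nucleus_mean_depth: float = 15.0
    nucleus_coverage_fraction: float = 0.4
    coverage_block_length: int = 10_000
    error_rate: float = 0.002
    mixture: float = 0.5
    snps_in_duplicates: bool = False
    n_collapsed_sites: int = 30
    n_mat_markers: int = 3

    def __post_init__(self) -> None:
        if self.scaffold_lengths is None:
            self.scaffold_lengths = default_scaffold_lengths(
                self.genome_size, self.n_scaffolds
            )
        self.scaffold_lengths = [int(x) for x in self.scaffold_lengths]
        self.n_scaffolds = len(self.scaffold_lengths)
        self.genome_size = sum(self.scaffold_lengths)
        if self.n_scaffolds < 1:
            raise ValueError("need at least one scaffold")
        if any(x <= 0 for x in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")
        if self.scaffold_lengths != sorted(self.scaffold_lengths, reverse=True):
            raise ValueError("scaffold_lengths must be sorted descending")
        for name, value in [
            ("dup_fraction", self.dup_fraction),
            ("nucleus_coverage_fraction", self.nucleus_coverage_fraction),
            ("error_rate", self.error_rate),
            ("mixture", self.mixture),
            ("divergence", self.divergence),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.divergence > 0.01:
            raise ValueError(
                "divergence > 1% is outside the dikaryon regime being emulated"
            )
        if self.dup_fraction >= 0.5:
            raise ValueError("dup_fraction must be < 0.5")
        if self.dup_segment_length < 402:
            raise ValueError(
                "duplicated segments must be >= 402 bp so a 201 bp window fits"
            )
        if self.dup_fraction > 0 and self.dup_segment_length > max(
            self.scaffold_lengths
        ):
            raise ValueError("duplicated segment longer than the largest scaffold")
        if self.bulk_mean_depth <= 0 or self.nucleus_mean_depth <= 0:
            raise ValueError("mean depths must be positive")
        n_nuclei = 2 * self.n_nuclei_per_mat
        for t in self.recomb_tracts:
            idx, _, start, end = t
            if not 0 <= idx < n_nuclei:
                raise ValueError(f"tract nucleus index {idx} out of range")
            if start > end or start < 1:
                raise ValueError(f"bad tract interval {t}")

    @property
    def scaffold_names(self) -> list[str]:
        width = max(3, len(str(self.n_scaffolds)))
        return [f"scaffold_{i + 1:0{width}d}" for i in range(self.n_scaffolds)]

    @property
    def nucleus_names(self) -> list[str]:
        n = 2 * self.n_nuclei_per_mat
        width = max(2, len(str(n)))
        return [f"nucleus_{i + 1:0{width}d}" for i in range(n)]

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["recomb_tracts"] = [list(t) for t in self.recomb_tracts]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["recomb_tracts"] = [tuple(t) for t in d.get("recomb_tracts", [])]
        return cls(**d)


@dataclass
class Truth:
    """Ground truth for one simulated isolate (parameter-recovery oracle)."""

    snp_pos: dict[str, np.ndarray]
    snp_ref: dict[str, np.ndarray]
    snp_alt: dict[str, np.ndarray]
    dup_intervals: dict[str, np.ndarray]
    collapsed_pos: dict[str, np.ndarray]
    collapsed_ref: dict[str, np.ndarray]
    collapsed_alt: dict[str, np.ndarray]
    mat_markers: list[tuple[str, int]] = field(default_factory=list)
    nuclei: list[str] = field(default_factory=list)
    clade: dict[str, str] = field(default_factory=dict)
    # nucleus -> scaffold -> bool array over that scaffold's truth SNPs
    # (True = the nucleus carries the nucleotype-2 / alternate allele there)
    haplotype: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    masks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return sum(len(p) for p in self.snp_pos.values())

    def mat_marker_table(self) -> pd.DataFrame:
        rows = []
        for scaffold, pos in self.mat_markers:
            i = int(np.searchsorted(self.snp_pos[scaffold], pos))
            rows.append(
                {
                    "scaffold": scaffold,
                    "pos": pos,
                    "ref": self.snp_ref[scaffold][i],
                    "alt": self.snp_alt[scaffold][i],
                    "ref_label": MAT_LABELS[0],
                    "alt_label": MAT_LABELS[1],
                }
            )
        return pd.DataFrame(
            rows, columns=["scaffold", "pos", "ref", "alt", "ref_label", "alt_label"]
        )

    def snp_table(self) -> pd.DataFrame:
        rows = []
        for scaffold in self.snp_pos:
            for p, r, a in zip(
                self.snp_pos[scaffold], self.snp_ref[scaffold], self.snp_alt[scaffold]
            ):
                rows.append({"scaffold": scaffold, "pos": int(p), "ref": r, "alt": a})
        return pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=tuple(key))
    )


# ---------------------------------------------------------------------------
# Reference and duplicated segments


def generate_reference(cfg: SimConfig) -> tuple[Reference, dict[str, np.ndarray]]:
    """Random reference scaffolds plus exact duplicated-segment intervals.

    ``dup_fraction`` of reference bases end up inside exact duplicated
    segments, counting both the source and the copy of each duplication
    event; both intervals are emitted.
    """
    rng = _rng(cfg, _SK_REFERENCE)
    names = cfg.scaffold_names
    seqs = {
        name: rng.integers(0, 4, size=length).astype(np.uint8)
        for name, length in zip(names, cfg.scaffold_lengths)
    }
    dup: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    target = cfg.dup_fraction * cfg.genome_size
    covered = 0
    L = cfg.dup_segment_length
    lengths = dict(zip(names, cfg.scaffold_lengths))
    eligible = [n for n in names if lengths[n] >= L]
    weights = np.array([lengths[n] for n in eligible], dtype=float)
    weights /= weights.sum() if len(weights) else 1.0

    def _free(name: str, start: int, end: int) -> bool:
        for s, e in dup[name]:
            if start <= e and s <= end:
                return False
        return True

    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        src_name, dst_name = (
            eligible[i] for i in rng.choice(len(eligible), size=2, p=weights)
        )
        src = int(rng.integers(1, lengths[src_name] - L + 2))
        dst = int(rng.integers(1, lengths[dst_name] - L + 2))
        src_iv = (src, src + L - 1)
        dst_iv = (dst, dst + L - 1)
        if not _free(src_name, *src_iv) or not _free(dst_name, *dst_iv):
            continue
        if src_name == dst_name and src_iv[0] <= dst_iv[1] and dst_iv[0] <= src_iv[1]:
            continue
        seqs[dst_name][dst - 1 : dst - 1 + L] = seqs[src_name][src - 1 : src - 1 + L]
        dup[src_name].append(src_iv)
        dup[dst_name].append(dst_iv)
        covered += 2 * L
    reference = Reference(
        {name: "".join(_BASES[seqs[name]]) for name in names}
    )
    dup_arrays = {
        name: iv.as_interval_array(sorted(dup[name])) for name in names if dup[name]
    }
    return reference, dup_arrays


# ---------------------------------------------------------------------------
# Nucleotypes, MAT markers, collapsed-duplicate artifact sites


def generate_nucleotypes(
    reference: Reference,
    cfg: SimConfig,
    dup_intervals: dict[str, np.ndarray] | None = None,
) -> Truth:
    """Draw nucleotype-differentiating SNPs and designate MAT markers.

    Nucleotype 1 equals the reference; nucleotype 2 differs by single-base
    substitutions at rate ``divergence``.  Truth SNPs avoid duplicated
    segments unless ``snps_in_duplicates`` is set.  MAT markers are one
    small cluster of truth SNPs on the largest scaffold.
    """
    if cfg.divergence > 0.01:
        raise ValueError("divergence > 1% rejected")
    dup_intervals = dup_intervals or {}
    snp_pos: dict[str, np.ndarray] = {}
    snp_ref: dict[str, np.ndarray] = {}
    snp_alt: dict[str, np.ndarray] = {}
    col_pos: dict[str, np.ndarray] = {}
    col_ref: dict[str, np.ndarray] = {}
    col_alt: dict[str, np.ndarray] = {}

    total_len = reference.total_length
    for si, name in enumerate(reference.names):
        rng = _rng(cfg, _SK_NUCLEOTYPES, si)
        length = len(reference[name])
        allowed = np.ones(length, dtype=bool)
        if not cfg.snps_in_duplicates and name in dup_intervals:
            for s, e in dup_intervals[name]:
                allowed[s - 1 : e] = False
        candidates = np.flatnonzero(allowed) + 1  # 1-based
        n_snps = rng.binomial(length, cfg.divergence)
        n_snps = min(n_snps, len(candidates))
        pos = np.sort(rng.choice(candidates, size=n_snps, replace=False))
        seq = np.frombuffer(reference[name].encode(), dtype="S1").astype("U1")
        refs = seq[pos - 1]
        alts = _substitute(rng, refs)
        snp_pos[name], snp_ref[name], snp_alt[name] = pos, refs, alts

        # collapsed-duplicate artifact sites, proportional to scaffold length
        n_col = int(round(cfg.n_collapsed_sites * length / total_len))
        free = candidates[~np.isin(candidates, pos)]
        n_col = min(n_col, len(free))
        cpos = np.sort(rng.choice(free, size=n_col, replace=False))
        crefs = seq[cpos - 1]
        col_pos[name], col_ref[name], col_alt[name] = (
            cpos,
            crefs,
            _substitute(rng, crefs),
        )

    truth = Truth(
        snp_pos=snp_pos,
        snp_ref=snp_ref,
        snp_alt=snp_alt,
        dup_intervals=dup_intervals,
        collapsed_pos=col_pos,
        collapsed_ref=col_ref,
        collapsed_alt=col_alt,
    )
    truth.mat_markers = _pick_mat_markers(reference, truth, cfg)
    return truth


def _substitute(rng: np.random.Generator, refs: np.ndarray) -> np.ndarray:
    """One random non-reference base per position."""
    alts = np.empty(len(refs), dtype="U1")
    shifts = rng.integers(1, 4, size=len(refs))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for j, (r, s) in enumerate(zip(refs, shifts)):
        alts[j] = "ACGT"[(base_index[r] + s) % 4]
    return alts


def _pick_mat_markers(
    reference: Reference, truth: Truth, cfg: SimConfig
) -> list[tuple[str, int]]:
    """One small cluster of nucleotype-differentiating positions per genome."""
    scaffold = reference.names[0]
    pos = truth.snp_pos.get(scaffold, np.empty(0, dtype=np.int64))
    if len(pos) == 0:
        return []
    n = min(cfg.n_mat_markers, len(pos))
    mid = len(reference[scaffold]) // 2
    centre = int(np.searchsorted(pos, mid))
    start = max(0, min(centre - n // 2, len(pos) - n))
    return [(scaffold, int(p)) for p in pos[start : start + n]]


# ---------------------------------------------------------------------------
# Nuclei


def generate_nuclei(cfg: SimConfig, truth: Truth) -> Truth:
    """Assign each nucleus its clade's nucleotype, then apply declared tracts.

    In a dikaryon (mixture < 1) the first half of the nuclei carry
    nucleotype 1 (MAT-1) and the second half nucleotype 2 (MAT-5); in a
    homokaryon (mixture == 1) every nucleus carries nucleotype 1.  Inside a
    declared recombination tract the nucleus carries the *opposite*
    nucleotype.
    """
    names = cfg.nucleus_names
    truth.nuclei = names
    scaffold_names = list(truth.snp_pos)
    homokaryon = cfg.mixture == 1.0
    truth.clade = {
        name: MAT_LABELS[0]
        if homokaryon or i < cfg.n_nuclei_per_mat
        else MAT_LABELS[1]
        for i, name in enumerate(names)
    }
    truth.haplotype = {}
    for i, name in enumerate(names):
        carries_alt = truth.clade[name] == MAT_LABELS[1]
        truth.haplotype[name] = {
            s: np.full(len(truth.snp_pos[s]), carries_alt) for s in scaffold_names
        }

    by_nucleus: dict[int, list[tuple[str, int, int]]] = {}
    for idx, scaffold, start, end in cfg.recomb_tracts:
        if scaffold not in truth.snp_pos:
            raise ValueError(f"tract references unknown scaffold {scaffold}")
        by_nucleus.setdefault(idx, [])
        for s0, st, en in by_nucleus[idx]:
            if s0 == scaffold and start <= en and st <= end:
                raise ValueError(
                    f"overlapping tracts on nucleus {idx}, scaffold {scaffold}"
                )
        by_nucleus[idx].append((scaffold, start, end))
        pos = truth.snp_pos[scaffold]
        inside = (pos >= start) & (pos <= end)
        hap = truth.haplotype[names[idx]][scaffold]
        hap[inside] = ~hap[inside]
    return truth


def plan_tract_over_snps(
    truth: Truth, scaffold: str, start_index: int, n_sites: int, pad: int = 50
) -> tuple[int, int]:
    """Interval spanning ``n_sites`` consecutive truth SNPs (test helper)."""
    pos = truth.snp_pos[scaffold]
    if start_index + n_sites > len(pos):
        raise ValueError("not enough truth SNPs on this scaffold")
    return int(pos[start_index] - pad), int(pos[start_index + n_sites - 1] + pad)


# ---------------------------------------------------------------------------
# Observations


@dataclass
class SimResult:
    cfg: SimConfig
    reference: Reference
    truth: Truth
    bulk: list[SiteObservation]
    nuclei_obs: dict[str, list[SiteObservation]]
    coverage: CoverageProfile

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lengths = self.reference.lengths
        write_reference(self.reference, outdir / "reference.fasta")
        write_vcf(self.bulk, lengths, outdir / "bulk.vcf", sample="bulk")
        nuc_dir = outdir / "nuclei"
        nuc_dir.mkdir(exist_ok=True)
        for name, obs in self.nuclei_obs.items():
            write_vcf(obs, lengths, nuc_dir / f"{name}.vcf", sample=name)
            write_bed(self.truth.masks[name], nuc_dir / f"{name}.coverage.bed")
        if self.truth.dup_intervals:
            write_bed(self.truth.dup_intervals, outdir / "duplicated_segments.bed")
        write_coverage(self.coverage, lengths, outdir / "bulk_coverage.tsv")
        self.truth.snp_table().to_csv(
            outdir / "truth_snps.tsv", sep="\t", index=False
        )
        self.truth.mat_marker_table().to_csv(
            outdir / "mat_markers.tsv", sep="\t", index=False
        )
        clades = pd.DataFrame(
            {"nucleus": self.truth.nuclei,
             "mat": [self.truth.clade[n] for n in self.truth.nuclei]}
        )
        clades.to_csv(outdir / "truth_clades.tsv", sep="\t", index=False)
        self.cfg.to_yaml(outdir / "config.yaml")


def _nucleus_mask(
    cfg: SimConfig, nucleus_index: int, lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Contiguous covered blocks drawn until the target fraction is reached.

    Blocks come from a per-nucleus stream in a fixed order, so masks for a
    larger coverage fraction are supersets of those for a smaller one.
    """
    names = list(lengths)
    if cfg.nucleus_coverage_fraction >= 1.0:
        return {n: np.array([[1, lengths[n]]], dtype=np.int64) for n in names}
    rng = _rng(cfg, _SK_MASKS, nucleus_index)
    sizes = np.array([lengths[n] for n in names], dtype=float)
    weights = sizes / sizes.sum()
    total = sizes.sum()
    target = cfg.nucleus_coverage_fraction * total
    blocks: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    covered = 0
    # random blocks overlap, so the block count needed inflates coupon-
    # collector style as the target fraction approaches 1
    while covered < target:
        si = int(rng.choice(len(names), p=weights))
        name = names[si]
        L = lengths[name]
        b = min(cfg.coverage_block_length, L)
        start = int(rng.integers(1, L - b + 2))
        blocks[name].append((start, start + b - 1))
        covered = sum(iv.total_length(b_) for b_ in blocks.values() if b_)
    return {n: iv.merge(b) for n, b in blocks.items() if b}


def _counts_for_carrier(
    rng: np.random.Generator, depth: np.ndarray, error_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """(true-allele reads, cross-contaminating other-pair-allele reads)."""
    true = rng.binomial(depth, 1.0 - error_rate)
    cross = rng.binomial(depth - true, 1.0 / 3.0)
    return true, cross


def simulate_observations(
    cfg: SimConfig, truth: Truth, reference: Reference
) -> SimResult:
    """Bulk and per-nucleus read-support observations at candidate sites.

    Bulk: depth ~ Poisson(bulk_mean_depth); the alternate-supporting count
    is Binomial(depth, p) with p the mixture-weighted true allele frequency
    perturbed by the error rate.  Nuclei: each nucleus observes its masked
    subset of positions at Poisson(nucleus_mean_depth) depth, with counts
    concentrated on its true allele and error_rate cross-contamination.
    """
    lengths = reference.lengths
    names = list(lengths)
    scaffold_index = {n: i for i, n in enumerate(names)}

    truth.masks = {
        nuc: _nucleus_mask(cfg, i, lengths) for i, nuc in enumerate(truth.nuclei)
    }

    nuclei_obs: dict[str, list[SiteObservation]] = {}
    error_sites: dict[str, set[int]] = {n: set() for n in names}
    for ni, nuc in enumerate(truth.nuclei):
        obs: list[SiteObservation] = []
        mask = truth.masks[nuc]
        for name in names:
            rng = _rng(cfg, _SK_NUCLEUS_OBS, ni, scaffold_index[name])
            pos = truth.snp_pos[name]
            # depths and counts drawn for every truth site in scaffold order
            # (masked subset selected afterwards -> nested-mask monotonicity)
            depth = rng.poisson(cfg.nucleus_mean_depth, size=len(pos))
            true, cross = _counts_for_carrier(rng, depth, cfg.error_rate)
            cpos = truth.collapsed_pos.get(name, np.empty(0, dtype=np.int64))
            cdepth = rng.poisson(cfg.nucleus_mean_depth, size=len(cpos))
            skew = rng.beta(0.3, 0.3, size=len(cpos)) if len(cpos) else np.empty(0)
            calt = rng.binomial(cdepth, skew) if len(cpos) else np.empty(0, int)

            in_mask = (
                iv.contains(mask[name], pos)
                if name in mask
                else np.zeros(len(pos), dtype=bool)
            )
            hap = truth.haplotype[nuc][name]
            for j in np.flatnonzero(in_mask):
                if hap[j]:
                    ro, ao = int(cross[j]), int(true[j])
                else:
                    ro, ao = int(true[j]), int(cross[j])
                obs.append(
                    SiteObservation(
                        name,
                        int(pos[j]),
                        str(truth.snp_ref[name][j]),
                        str(truth.snp_alt[name][j]),
                        ro,
                        ao,
                        int(depth[j]),
                    )
                )
            if len(cpos):
                cin = (
                    iv.contains(mask[name], cpos)
                    if name in mask
                    else np.zeros(len(cpos), dtype=bool)
                )
                for j in np.flatnonzero(cin):
                    obs.append(
                        SiteObservation(
                            name,
                            int(cpos[j]),
                            str(truth.collapsed_ref[name][j]),
                            str(truth.collapsed_alt[name][j]),
                            int(cdepth[j] - calt[j]),
                            int(calt[j]),
                            int(cdepth[j]),
                        )
                    )
            # spurious error-only candidate sites inside the mask
            if cfg.error_rate > 0 and name in mask:
                covered_len = iv.total_length(mask[name])
                m = cfg.nucleus_mean_depth * cfg.error_rate / 3.0
                p2 = 1.0 - np.exp(-m) * (1.0 + m)  # >= 2 errors to one base
                n_err = rng.poisson(covered_len * p2 * 3.0)  # any of 3 alt bases
                taken = set(pos.tolist()) | set(cpos.tolist())
                merged = mask[name]
                starts = merged[:, 0]
                widths = merged[:, 1] - merged[:, 0] + 1
                cum = np.concatenate(([0], np.cumsum(widths)))
                for _ in range(n_err):
                    off = int(rng.integers(0, cum[-1]))
                    k = int(np.searchsorted(cum, off, side="right")) - 1
                    p = int(starts[k] + off - cum[k])
                    if p in taken:
                        continue
                    taken.add(p)
                    ref_base = reference[name][p - 1]
                    alt_base = "ACGT"[("ACGT".index(ref_base) + int(rng.integers(1, 4))) % 4]
                    ao = 2 + int(rng.poisson(m))
                    dp = max(int(rng.poisson(cfg.nucleus_mean_depth)), ao)
                    obs.append(
                        SiteObservation(name, p, ref_base, alt_base, dp - ao, ao, dp)
                    )
                    error_sites[name].add(p)
        obs.sort(key=lambda o: (scaffold_index[o.scaffold], o.pos))
        nuclei_obs[nuc] = obs

    # bulk observations at the union of candidate sites
    rng = _rng(cfg, _SK_BULK)
    bulk: list[SiteObservation] = []
    e = cfg.error_rate
    for name in names:
        site_alleles: list[tuple[int, str, str, float]] = []
        p_alt_truth = (1.0 - cfg.mixture) * (1.0 - e) + cfg.mixture * e / 3.0
        for j, p in enumerate(truth.snp_pos[name]):
            site_alleles.append(
                (int(p), str(truth.snp_ref[name][j]), str(truth.snp_alt[name][j]), p_alt_truth)
            )
        for j, p in enumerate(truth.collapsed_pos.get(name, ())):
            site_alleles.append(
                (
                    int(p),
                    str(truth.collapsed_ref[name][j]),
                    str(truth.collapsed_alt[name][j]),
                    0.5,
                )
            )
        for p in sorted(error_sites[name]):
            ref_base = reference[name][p - 1]
            alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
            site_alleles.append((p, ref_base, alt_base, e / 3.0))
        site_alleles.sort()
        for p, ref_base, alt_base, p_alt in site_alleles:
            dp = int(rng.poisson(cfg.bulk_mean_depth))
            ao = int(rng.binomial(dp, p_alt))
            other = int(rng.binomial(dp - ao, e * 2.0 / 3.0))
            if ao >= 1:
                bulk.append(
                    SiteObservation(name, p, ref_base, alt_base, dp - ao - other, ao, dp)
                )

    per_scaffold_mean = {}
    for name in names:
        L = lengths[name]
        per_scaffold_mean[name] = float(rng.poisson(L * cfg.bulk_mean_depth)) / L
    genome_mean = float(
        sum(per_scaffold_mean[n] * lengths[n] for n in names) / sum(lengths.values())
    )
    coverage = CoverageProfile(per_scaffold_mean, genome_mean)
    return SimResult(cfg, reference, truth, bulk, nuclei_obs, coverage)


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: reference -> nucleotypes -> nuclei -> reads."""
    reference, dup_intervals = generate_reference(cfg)
    truth = generate_nucleotypes(reference, cfg, dup_intervals)
    truth = generate_nuclei(cfg, truth)
    return simulate_observations(cfg, truth, reference)
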