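"""The 'basic' and 'stringent' SNP filter cascades and the bulk AF spectrum.

Basic tier (per nucleus): an alternate allele is kept when it has at least
``min_alt_reads`` supporting reads and outnumbers reference-supporting reads
by at least ``support_ratio`` : 1 (10:1 by default, inclusive).

Stringent tier (on top of basic): the site must lie on one of the
``top_n_scaffolds`` largest scaffolds; the *bulk* (original assembly reads)
depth at the position must fall within 69–131% of the genome-wide mean bulk
depth; the bulk alternate allele frequency must fall within 0.26–0.74; and
the 100 bp flanks of the SNP must align to at most ``max_hits`` places in
the reference (a unique locus self-hits once per flank, so 2 hits; more
than 2 good hits at e-value <= 0.001 marks a multi-copy region).

All windows are inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import KmerAligner
from .io import CoverageProfile, Reference, SiteObservation

# failure-reason codes
MIN_ALT = "MIN_ALT"
RATIO = "RATIO"
NOT_TOP_SCAFFOLD = "NOT_TOP_SCAFFOLD"
COV_WINDOW = "COV_WINDOW"
AF_WINDOW = "AF_WINDOW"
MULTI_COPY = "MULTI_COPY"
NON_SNV = "NON_SNV"

ALL_REASONS = (MIN_ALT, RATIO, NOT_TOP_SCAFFOLD, COV_WINDOW, AF_WINDOW, MULTI_COPY, NON_SNV)


@dataclass
class FilterParams:
    """Every threshold of the basic and stringent filters in one place."""

    min_alt_reads: int = 2
    support_ratio: float = 10.0
    cov_window_lo: float = 0.69
    cov_window_hi: float = 1.31
    af_lo: float = 0.26
    af_hi: float = 0.74
    flank_bp: int = 100
    evalue_max: float = 1e-3
    max_hits: int = 2
    top_n_scaffolds: int = 100
    min_flank_bp: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.cov_window_lo < 1 < self.cov_window_hi:
            raise ValueError("need 0 < cov_window_lo < 1 < cov_window_hi")
        if not 0 < self.af_lo < self.af_hi < 1:
            raise ValueError("need 0 < af_lo < af_hi < 1")
        if self.support_ratio < 1:
            raise ValueError("support_ratio must be >= 1")


@dataclass
class FilterVerdict:
    """Auditable per-site filter outcome."""

    site: SiteObservation
    passed_basic: bool
    passed_stringent: bool = False
    failure_reasons: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def basic_filter(obs: SiteObservation, params: FilterParams) -> FilterVerdict:
    """Per-nucleus read-support filter (the rescue clause lives in genotyping)."""
    reasons: list[str] = []
    if not obs.is_snv:
        reasons.append(NON_SNV)
    if obs.alt_depth < params.min_alt_reads:
        reasons.append(MIN_ALT)
    if obs.alt_depth < params.support_ratio * obs.ref_depth:
        reasons.append(RATIO)
    return FilterVerdict(obs, passed_basic=not reasons, failure_reasons=reasons)


class SingleCopyChecker:
    """Flanking-sequence uniqueness test with a cached alignment backend.

    The upstream and the downstream flank are queried separately; a unique
    region therefore self-hits twice in total.  Flanks are truncated at
    scaffold ends; if either truncates below ``min_flank_bp`` the site
    fails safe as multi-copy.
    """

    def __init__(self, reference: Reference, params: FilterParams, backend=None):
        self.reference = reference
        self.params = params
        self.backend = backend if backend is not None else KmerAligner(reference)
        self._cache: dict[tuple[str, int], tuple[bool, int | None, str | None]] = {}

    def check(self, scaffold: str, pos: int) -> tuple[bool, int | None, str | None]:
        """Returns (passed, combined hit count or None, note or None)."""
        key = (scaffold, pos)
        if key in self._cache:
            return self._cache[key]
        p = self.params
        length = len(self.reference[scaffold])
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside scaffold {scaffold}")
        up = self.reference.fetch(scaffold, pos - p.flank_bp, pos - 1)
        down = self.reference.fetch(scaffold, pos + 1, pos + p.flank_bp)
        if len(up) < p.min_flank_bp or len(down) < p.min_flank_bp:
            result = (False, None, "flank truncated below minimum; fail-safe")
        else:
            hits = self.backend.count_hits(up, p.evalue_max) + self.backend.count_hits(
                down, p.evalue_max
            )
            result = (hits <= p.max_hits, hits, None)
        self._cache[key] = result
        return result


def single_copy_check(
    scaffold: str,
    pos: int,
    reference: Reference,
    params: FilterParams,
    checker: SingleCopyChecker | None = None,
) -> tuple[bool, int | None]:
    """One-shot flank-uniqueness test (builds its own aligner if no checker)."""
    checker = checker or SingleCopyChecker(reference, params)
    passed, hits, _ = checker.check(scaffold, pos)
    return passed, hits


def _bulk_depth(bulk: SiteObservation) -> int:
    if bulk.total_depth is not None:
        return bulk.total_depth
    return bulk.ref_depth + bulk.alt_depth


def stringent_filter(
    site: SiteObservation,
    bulk_obs: SiteObservation | None,
    coverage: CoverageProfile,
    reference: Reference,
    params: FilterParams,
    checker: SingleCopyChecker | None = None,
) -> FilterVerdict:
    """The three bulk-level criteria plus the single-copy test.

    ``site`` must already have passed the basic tier.  The expensive
    single-copy test is only run when the cheaper criteria all pass (the
    verdict's pass/fail is unaffected; its reason list is then the cheap
    failures only).
    """
    reasons: list[str] = []
    notes: list[str] = []
    if site.scaffold not in reference.top_scaffolds(params.top_n_scaffolds):
        reasons.append(NOT_TOP_SCAFFOLD)
    if bulk_obs is None:
        reasons.append(COV_WINDOW)
        reasons.append(AF_WINDOW)
        notes.append("no bulk data at position")
    else:
        depth = _bulk_depth(bulk_obs)
        lo = params.cov_window_lo * coverage.genome_mean
        hi = params.cov_window_hi * coverage.genome_mean
        if not lo <= depth <= hi:
            reasons.append(COV_WINDOW)
        af = bulk_obs.allele_frequency
        if af is None or not params.af_lo <= af <= params.af_hi:
            reasons.append(AF_WINDOW)
            if af is None:
                notes.append("no informative bulk reads")
    if not reasons:
        passed, hits, note = (checker or SingleCopyChecker(reference, params)).check(
            site.scaffold, site.pos
        )
        if not passed:
            reasons.append(MULTI_COPY)
            if note:
                notes.append(note)
    return FilterVerdict(
        site,
        passed_basic=True,
        passed_stringent=not reasons,
        failure_reasons=reasons,
        notes=notes,
    )


class BulkIndex:
    """Lookup of bulk observations by (scaffold, pos[, alt])."""

    def __init__(self, bulk_obs: Iterable[SiteObservation]):
        self._by_allele: dict[tuple[str, int, str | None], SiteObservation] = {}
        self._by_pos: dict[tuple[str, int], SiteObservation] = {}
        for o in bulk_obs:
            self._by_allele[(o.scaffold, o.pos, o.alt_allele)] = o
            self._by_pos.setdefault((o.scaffold, o.pos), o)

    def lookup(self, site: SiteObservation) -> SiteObservation | None:
        hit = self._by_allele.get((site.scaffold, site.pos, site.alt_allele))
        if hit is None:
            hit = self._by_pos.get((site.scaffold, site.pos))
        return hit


def run_cascade(
    nuclei_obs: Mapping[str, Sequence[SiteObservation]],
    bulk_obs: Sequence[SiteObservation],
    coverage: CoverageProfile,
    reference: Reference,
    params: FilterParams | None = None,
    checker: SingleCopyChecker | None = None,
) -> dict[str, list[FilterVerdict]]:
    """Run basic + stringent filtering for every nucleus.

    Single-copy results are cached per position across nuclei.
    """
    params = params or FilterParams()
    checker = checker or SingleCopyChecker(reference, params)
    bulk_index = BulkIndex(bulk_obs)
    verdicts: dict[str, list[FilterVerdict]] = {}
    for nucleus, observations in nuclei_obs.items():
        out: list[FilterVerdict] = []
        for obs in observations:
            v = basic_filter(obs, params)
            if v.passed_basic:
                v = stringent_filter(
                    obs, bulk_index.lookup(obs), coverage, reference, params, checker
                )
            out.append(v)
        verdicts[nucleus] = out
    return verdicts


def retained_sites(
    verdicts: Mapping[str, Sequence[FilterVerdict]], tier: str = "stringent"
) -> list[tuple[str, int, str, str | None]]:
    """Distinct sites passing the tier in at least one nucleus, sorted."""
    if tier not in ("basic", "stringent"):
        raise ValueError("tier must be 'basic' or 'stringent'")
    keep: set[tuple[str, int, str, str | None]] = set()
    for vs in verdicts.values():
        for v in vs:
            ok = v.passed_basic if tier == "basic" else v.passed_stringent
            if ok:
                keep.add(v.site.key)
    return sorted(keep, key=lambda k: (k[0], k[1], k[3] or ""))


def funnel_summary(verdicts: Mapping[str, Sequence[FilterVerdict]]) -> pd.DataFrame:
    """Counts of verdicts and failure reasons per nucleus."""
    rows = []
    for nucleus, vs in verdicts.items():
        row = {"nucleus": nucleus, "n_sites": len(vs)}
        row["passed_basic"] = sum(v.passed_basic for v in vs)
        row["passed_stringent"] = sum(v.passed_stringent for v in vs)
        for reason in ALL_REASONS:
            row[reason] = sum(reason in v.failure_reasons for v in vs)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AFSpectrum:
    """Histogram of bulk alternate-allele frequencies."""

    counts: np.ndarray
    bin_edges: np.ndarray
    modal_bin_center: float | None
    dikaryon_like: bool
    n_sites: int

    @property
    def empty(self) -> bool:
        return self.n_sites == 0


def allele_frequency_spectrum(
    bulk_obs: Sequence[SiteObservation], bin_width: float = 0.05
) -> AFSpectrum:
    """AF histogram with fixed bins over (0, 1) and a dikaryon-likeness call.

    A dikaryotic bulk shows its hallmark allele-frequency peak at 0.5; the
    isolate is flagged dikaryon-like when the modal bin center falls within
    [0.45, 0.55].
    """
    afs = np.array(
        [o.allele_frequency for o in bulk_obs if o.ref_depth + o.alt_depth > 0],
        dtype=float,
    )
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if len(afs) == 0:
        return AFSpectrum(np.zeros(len(edges) - 1, dtype=int), edges, None, False, 0)
    counts, _ = np.histogram(afs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    modal = float(centers[int(np.argmax(counts))])
    return AFSpectrum(counts, edges, modal, bool(0.45 <= modal <= 0.55), len(afs))
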