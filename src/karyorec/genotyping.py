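"""Per-nucleus genotype calls with the co-nucleus rescue clause, plus MAT assignment.

A nucleus is called STRONG for an allele when that allele's reads outnumber
the opposite allele's by the 10:1 support ratio (applied symmetrically to
REF and ALT; reference-genotype confidence is required to score a nucleus
as reference-like).  A nucleus failing the ratio keeps its majority allele
as a RESCUED call when at least one co-existing nucleus is STRONG for the
same allele at the same position; otherwise the entry is MISSING.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import FilterParams, FilterVerdict, retained_sites
from .io import SiteObservation

# call codes
MISSING, REF, ALT = 0, 1, 2
# support codes
NONE, STRONG, RESCUED = 0, 1, 2

CALL_SYMBOLS = {MISSING: ".", REF: "R", ALT: "A"}
SUPPORT_SYMBOLS = {NONE: ".", STRONG: "S", RESCUED: "r"}

UNASSIGNED = "UNASSIGNED"


@dataclass
class GenotypeCall:
    call: int
    support: int
    tie: bool = False


def call_genotype(
    obs: SiteObservation | None,
    strong_co_calls: set[int] | Sequence[int] = (),
    params: FilterParams | None = None,
) -> GenotypeCall:
    """Genotype one nucleus at one retained site.

    ``strong_co_calls`` is the set of calls (REF/ALT) for which at least one
    co-existing nucleus is STRONG at this site.  On a ref==alt tie the call
    is rescued only when exactly one of the two alleles has a strong
    co-nucleus; otherwise the tie is flagged and the entry is MISSING.
    """
    params = params or FilterParams()
    strong_co = set(strong_co_calls)
    if obs is None:
        return GenotypeCall(MISSING, NONE)
    ro, ao = obs.ref_depth, obs.alt_depth
    if ro + ao == 0:
        return GenotypeCall(MISSING, NONE)
    threshold_alt = max(params.min_alt_reads, params.support_ratio * ro)
    threshold_ref = max(params.min_alt_reads, params.support_ratio * ao)
    if ao >= threshold_alt:
        return GenotypeCall(ALT, STRONG)
    if ro >= threshold_ref:
        return GenotypeCall(REF, STRONG)
    if ro == ao:
        candidates = strong_co & {REF, ALT}
        if len(candidates) == 1:
            return GenotypeCall(candidates.pop(), RESCUED, tie=True)
        return GenotypeCall(MISSING, NONE, tie=True)
    majority = ALT if ao > ro else REF
    if majority in strong_co:
        return GenotypeCall(majority, RESCUED)
    return GenotypeCall(MISSING, NONE)


@dataclass
class GenotypeMatrix:
    """Nuclei x retained-sites genotype calls with support provenance."""

    nuclei: list[str]
    sites: pd.DataFrame  # columns scaffold, pos, ref, alt
    calls: np.ndarray  # int8, {MISSING, REF, ALT}
    support: np.ndarray  # int8, {NONE, STRONG, RESCUED}
    coverage_masks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    ties: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.nuclei)) != len(self.nuclei):
            raise ValueError("duplicate nucleus identifiers")
        if self.calls.shape != (len(self.nuclei), len(self.sites)):
            raise ValueError("calls shape does not match nuclei x sites")
        if ((self.calls != MISSING) & (self.support == NONE)).any():
            raise ValueError("non-missing call without support")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def nucleus_index(self, name: str) -> int:
        return self.nuclei.index(name)

    def site_lookup(self) -> dict[tuple[str, int], int]:
        return {
            (s, int(p)): i
            for i, (s, p) in enumerate(zip(self.sites["scaffold"], self.sites["pos"]))
        }

    def to_tsv(self, calls_path: str | Path, support_path: str | Path | None = None) -> None:
        cols = [
            f"{s}:{p}" for s, p in zip(self.sites["scaffold"], self.sites["pos"])
        ]
        calls = pd.DataFrame(
            [[CALL_SYMBOLS[c] for c in row] for row in self.calls],
            index=self.nuclei,
            columns=cols,
        )
        calls.to_csv(calls_path, sep="\t", index_label="nucleus")
        if support_path is not None:
            sup = pd.DataFrame(
                [[SUPPORT_SYMBOLS[c] for c in row] for row in self.support],
                index=self.nuclei,
                columns=cols,
            )
            sup.to_csv(support_path, sep="\t", index_label="nucleus")


def build_matrix(
    verdicts: Mapping[str, Sequence[FilterVerdict]],
    nuclei_obs: Mapping[str, Sequence[SiteObservation]],
    params: FilterParams | None = None,
    tier: str = "stringent",
    coverage_masks: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> GenotypeMatrix:
    """Genotype every nucleus at the union of sites retained at ``tier``.

    The site universe is the union of sites retained in at least one
    nucleus; every nucleus is genotyped at every universe site (MISSING
    where it has no observation).  Rescue is applied in a second pass once
    all STRONG calls are known.
    """
    params = params or FilterParams()
    nuclei = list(nuclei_obs)
    if len(set(nuclei)) != len(nuclei):
        raise ValueError("duplicate nucleus identifiers")
    site_keys = retained_sites(verdicts, tier)
    sites = pd.DataFrame(site_keys, columns=["scaffold", "pos", "ref", "alt"])
    n, m = len(nuclei), len(site_keys)
    calls = np.zeros((n, m), dtype=np.int8)
    support = np.zeros((n, m), dtype=np.int8)
    ties = np.zeros((n, m), dtype=bool)

    # observation lookup per nucleus; an observation whose alternate allele
    # differs from the universe site's contributes only its reference reads
    index: list[dict[tuple[str, int], SiteObservation]] = []
    for nucleus in nuclei:
        index.append({(o.scaffold, o.pos): o for o in nuclei_obs[nucleus]})

    def effective_obs(i: int, key: tuple[str, int, str, str | None]):
        o = index[i].get((key[0], key[1]))
        if o is None:
            return None
        if o.alt_allele == key[3]:
            return o
        return SiteObservation(
            o.scaffold, o.pos, o.ref_allele, key[3], o.ref_depth, 0, o.total_depth
        )

    first_pass: list[list[GenotypeCall | None]] = [[None] * m for _ in range(n)]
    strong_at_site: list[dict[int, int]] = [dict() for _ in range(m)]
    for i in range(n):
        for j, key in enumerate(site_keys):
            gc = call_genotype(effective_obs(i, key), (), params)
            first_pass[i][j] = gc
            if gc.support == STRONG:
                strong_at_site[j][i] = gc.call

    for j in range(m):
        for i in range(n):
            gc = first_pass[i][j]
            if gc.support == STRONG:
                calls[i, j], support[i, j] = gc.call, gc.support
            else:
                co = set(
                    c for i2, c in strong_at_site[j].items() if i2 != i
                )
                gc2 = call_genotype(effective_obs(i, site_keys[j]), co, params)
                calls[i, j], support[i, j] = gc2.call, gc2.support
                ties[i, j] = gc2.tie

    masks = (
        {k: {s: np.asarray(v) for s, v in m_.items()} for k, m_ in coverage_masks.items()}
        if coverage_masks
        else {}
    )
    return GenotypeMatrix(nuclei, sites, calls, support, masks, ties)


@dataclass
class MatAssignment:
    """Per-nucleus mating-type label from designated marker positions."""

    assignment: dict[str, str]
    conflict: dict[str, bool]
    markers_used: list[tuple[str, int]]


def assign_mat(matrix: GenotypeMatrix, marker_table: pd.DataFrame) -> MatAssignment:
    """Majority vote over non-missing marker genotypes.

    ``marker_table`` columns: scaffold, pos, ref_label, alt_label.  Markers
    absent from the matrix are skipped with a warning.  No strict majority
    (including the all-missing case) leaves the nucleus UNASSIGNED; any
    disagreement among markers raises the conflict flag.
    """
    lookup = matrix.site_lookup()
    used: list[tuple[str, int]] = []
    cols: list[int] = []
    labels: list[tuple[str, str]] = []
    for _, row in marker_table.iterrows():
        key = (row["scaffold"], int(row["pos"]))
        if key not in lookup:
            warnings.warn(f"MAT marker {key[0]}:{key[1]} absent from matrix; skipped")
            continue
        used.append(key)
        cols.append(lookup[key])
        labels.append((row["ref_label"], row["alt_label"]))
    assignment: dict[str, str] = {}
    conflict: dict[str, bool] = {}
    for i, nucleus in enumerate(matrix.nuclei):
        votes: dict[str, int] = {}
        for j, (ref_label, alt_label) in zip(cols, labels):
            c = matrix.calls[i, j]
            if c == REF:
                votes[ref_label] = votes.get(ref_label, 0) + 1
            elif c == ALT:
                votes[alt_label] = votes.get(alt_label, 0) + 1
        total = sum(votes.values())
        conflict[nucleus] = len(votes) > 1
        if total == 0:
            assignment[nucleus] = UNASSIGNED
            continue
        best_label, best_votes = max(votes.items(), key=lambda kv: kv[1])
        if 2 * best_votes > total:
            assignment[nucleus] = best_label
        else:
            assignment[nucleus] = UNASSIGNED
    return MatAssignment(assignment, conflict, used)
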