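"""Clade-consensus diagnostic sites, recombination-tract calling, dispersion.

A *diagnostic site* is a retained SNP position at which the two mating-type
clades have distinct, well-supported consensus genotypes (each backed by at
least ``min_votes`` STRONG calls with >= 80% within-clade agreement).  A
*recombination tract* in a nucleus is a maximal run of at least ``min_run``
consecutive diagnostic sites at which the nucleus carries the opposite
clade's genotype; MISSING sites neither break nor extend a run.  Because
true breakpoints are unresolvable between diagnostic sites, each tract
reports the span of its supporting sites (inner bound) together with the
flanking own-clade site positions (outer bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import ALT, MISSING, REF, STRONG, GenotypeMatrix
from .io import Reference, SiteObservation


@dataclass
class DiagnosticSite:
    scaffold: str
    pos: int
    site_index: int  # column in the genotype matrix
    clade1_call: int
    clade2_call: int
    n_votes_clade1: int
    n_votes_clade2: int


@dataclass
class RecombinationTract:
    nucleus: str
    scaffold: str
    start: int  # first supporting diagnostic site, 1-based inclusive
    end: int  # last supporting diagnostic site
    n_supporting: int
    own_clade: int
    donor_clade: int
    outer_start: int  # nearest flanking own-clade site (or scaffold-start 1)
    outer_end: int


def _clade_consensus(
    calls: np.ndarray, support: np.ndarray, members: np.ndarray, j: int,
    min_votes: int, min_agreement: float,
) -> tuple[int | None, int]:
    votes = calls[members, j][(support[members, j] == STRONG)]
    votes = votes[votes != MISSING]
    if len(votes) < min_votes:
        return None, len(votes)
    n_ref = int((votes == REF).sum())
    n_alt = int((votes == ALT).sum())
    top, n_top = (REF, n_ref) if n_ref >= n_alt else (ALT, n_alt)
    if n_top / len(votes) < min_agreement:
        return None, len(votes)
    return top, len(votes)


def find_diagnostic_sites(
    matrix: GenotypeMatrix,
    clades: Mapping[str, int],
    min_votes: int = 2,
    min_agreement: float = 0.8,
) -> list[DiagnosticSite]:
    """Sites where the two clades hold distinct, well-supported consensuses."""
    members1 = np.array([i for i, n in enumerate(matrix.nuclei) if clades.get(n) == 1])
    members2 = np.array([i for i, n in enumerate(matrix.nuclei) if clades.get(n) == 2])
    if len(members1) == 0 or len(members2) == 0:
        raise ValueError("each clade needs at least one nucleus")
    out: list[DiagnosticSite] = []
    scaffolds = matrix.sites["scaffold"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    for j in range(matrix.n_sites):
        c1, v1 = _clade_consensus(
            matrix.calls, matrix.support, members1, j, min_votes, min_agreement
        )
        c2, v2 = _clade_consensus(
            matrix.calls, matrix.support, members2, j, min_votes, min_agreement
        )
        if c1 is not None and c2 is not None and c1 != c2:
            out.append(
                DiagnosticSite(scaffolds[j], int(positions[j]), j, c1, c2, v1, v2)
            )
    out.sort(key=lambda d: (d.scaffold, d.pos))
    return out


def call_tracts(
    matrix: GenotypeMatrix,
    diagnostic_sites: Sequence[DiagnosticSite],
    clades: Mapping[str, int],
    min_run: int = 2,
) -> list[RecombinationTract]:
    """Maximal opposite-clade runs of length >= min_run per nucleus per scaffold."""
    by_scaffold: dict[str, list[DiagnosticSite]] = {}
    for d in diagnostic_sites:
        by_scaffold.setdefault(d.scaffold, []).append(d)
    for sites in by_scaffold.values():
        sites.sort(key=lambda d: d.pos)

    tracts: list[RecombinationTract] = []
    for i, nucleus in enumerate(matrix.nuclei):
        clade = clades.get(nucleus)
        if clade not in (1, 2):
            warnings.warn(f"nucleus {nucleus} has no clade label; skipped")
            continue
        donor = 3 - clade
        for scaffold, sites in by_scaffold.items():
            run: list[DiagnosticSite] = []
            last_own: DiagnosticSite | None = None
            pending_own: DiagnosticSite | None = None

            def flush(next_own: DiagnosticSite | None) -> None:
                nonlocal run
                if len(run) >= min_run:
                    tracts.append(
                        RecombinationTract(
                            nucleus=nucleus,
                            scaffold=scaffold,
                            start=run[0].pos,
                            end=run[-1].pos,
                            n_supporting=len(run),
                            own_clade=clade,
                            donor_clade=donor,
                            outer_start=pending_own.pos if pending_own else 1,
                            outer_end=next_own.pos if next_own else sites[-1].pos,
                        )
                    )
                run = []

            for d in sites:
                call = matrix.calls[i, d.site_index]
                if call == MISSING:
                    continue
                own_call = d.clade1_call if clade == 1 else d.clade2_call
                if call == own_call:
                    flush(d)
                    pending_own = d
                else:
                    run.append(d)
            flush(None)
    tracts.sort(key=lambda t: (t.nucleus, t.scaffold, t.start))
    return tracts


def genotype_table(
    matrix: GenotypeMatrix,
    diagnostic_sites: Sequence[DiagnosticSite],
    clades: Mapping[str, int],
    scaffold: str,
    clade_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Mosaic genotype table for one scaffold: rows = nuclei grouped by clade,
    columns = diagnostic positions, cells = the clade whose consensus the
    nucleus matches ('' where uncovered)."""
    sites = sorted(
        (d for d in diagnostic_sites if d.scaffold == scaffold), key=lambda d: d.pos
    )
    if not sites and scaffold not in set(matrix.sites["scaffold"]):
        raise ValueError(f"scaffold {scaffold} absent from the genotype matrix")
    clade_names = clade_names or {1: "clade1", 2: "clade2"}
    order = sorted(
        range(len(matrix.nuclei)),
        key=lambda i: (clades.get(matrix.nuclei[i], 99), matrix.nuclei[i]),
    )
    rows = {}
    for i in order:
        name = matrix.nuclei[i]
        cells = []
        for d in sites:
            call = matrix.calls[i, d.site_index]
            if call == MISSING:
                cells.append("")
            elif call == d.clade1_call:
                cells.append(clade_names[1])
            else:
                cells.append(clade_names[2])
        label = clades.get(name)
        rows[f"{name} ({clade_names.get(label, 'NA')})"] = cells
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[d.pos for d in sites]
    )


def dispersion(
    observations: Sequence[SiteObservation],
    reference: Reference,
    scaffold_one_only: bool = False,
    plot_alpha: float = 0.2,
) -> pd.DataFrame:
    """Normalized SNP positions: percent of the scaffold length.

    Variants longer than one base are removed before normalization.  By
    default every scaffold is normalized by its own length; with
    ``scaffold_one_only`` only the largest scaffold is kept.  The plotting
    alpha used for dispersion figures is recorded in the frame attributes.
    """
    keep_scaffolds = (
        {reference.names[0]} if scaffold_one_only else set(reference.names)
    )
    rows = []
    for o in observations:
        if o.var_length != 1 or o.scaffold not in keep_scaffolds:
            continue
        length = len(reference[o.scaffold])
        if o.pos > length:
            raise ValueError(
                f"position {o.pos} beyond scaffold {o.scaffold} ({length} bp)"
            )
        rows.append(
            {
                "scaffold": o.scaffold,
                "pos": o.pos,
                "percent_of_scaffold": 100.0 * o.pos / length,
            }
        )
    df = pd.DataFrame(rows, columns=["scaffold", "pos", "percent_of_scaffold"])
    df.attrs["plot_alpha"] = plot_alpha
    return df
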