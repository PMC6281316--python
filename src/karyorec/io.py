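"""Readers/writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* SNP positions are 1-based inclusive (VCF convention) everywhere inside the
  package; 0-based half-open coordinates appear only in BED files.
* Scaffolds are ordered by decreasing length, ties broken lexicographically
  by name, so "the N largest scaffolds" is well defined.
* Read support is carried as FreeBayes-style RO (reference-supporting) / AO
  (alternate-supporting) counts; AD-style fields are accepted as a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import intervals as iv

_BASES = frozenset("ACGT")


@dataclass
class SiteObservation:
    """One variant position with ref/alt read support, for bulk or one nucleus."""

    scaffold: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str | None
    ref_depth: int
    alt_depth: int
    total_depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")
        if (
            self.total_depth is not None
            and self.ref_depth + self.alt_depth > self.total_depth
        ):
            raise ValueError(
                f"RO + AO exceeds DP at {self.scaffold}:{self.pos} "
                f"({self.ref_depth}+{self.alt_depth} > {self.total_depth})"
            )

    @property
    def var_length(self) -> int:
        """Length of the variant: 1 for SNVs, >1 for MNVs/indels."""
        alt = self.alt_allele or self.ref_allele
        return max(len(self.ref_allele), len(alt))

    @property
    def is_snv(self) -> bool:
        return (
            self.alt_allele is not None
            and len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _BASES
            and self.alt_allele in _BASES
        )

    @property
    def allele_frequency(self) -> float | None:
        """AF = AO / (RO + AO); None when no informative reads."""
        denom = self.ref_depth + self.alt_depth
        if denom == 0:
            return None
        return self.alt_depth / denom

    @property
    def key(self) -> tuple[str, int, str, str | None]:
        return (self.scaffold, self.pos, self.ref_allele, self.alt_allele)


class Reference:
    """A genome as scaffold name -> sequence, ordered by decreasing length."""

    def __init__(self, scaffolds: Mapping[str, str]):
        names = list(scaffolds)
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names")
        order = sorted(names, key=lambda n: (-len(scaffolds[n]), n))
        self._seqs: dict[str, str] = {n: str(scaffolds[n]).upper() for n in order}

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def top_scaffolds(self, n: int) -> list[str]:
        """The n largest scaffolds (all of them if fewer exist)."""
        return self.names[:n]

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Subsequence [start, end], 1-based inclusive, clipped to the scaffold."""
        seq = self._seqs[scaffold]
        return seq[max(start, 1) - 1 : min(end, len(seq))]


@dataclass
class CoverageProfile:
    """Bulk read depth summarised per scaffold plus the genome-wide mean."""

    per_scaffold_mean: dict[str, float]
    genome_mean: float

    def __post_init__(self) -> None:
        if self.per_scaffold_mean and self.genome_mean <= 0:
            raise ValueError("genome-wide mean depth must be positive")


# ---------------------------------------------------------------------------
# FASTA


def read_reference(path: str | Path) -> Reference:
    """Load a FASTA into a :class:`Reference` (length-descending order)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate scaffold name in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return Reference(seqs)


def write_reference(reference: Reference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(reference[name]), id=name, description="")
        for name in reference.names
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(
    contig_lengths: Mapping[str, int], sample: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth at the position")
    header.formats.add("RO", 1, "Integer", "Reference-supporting read count")
    header.formats.add("AO", "A", "Integer", "Alternate-supporting read count")
    header.add_sample(sample)
    return header


def write_vcf(
    observations: Iterable[SiteObservation],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sample: str = "sample",
) -> None:
    """Write observations as a VCF v4.2 with FORMAT DP/RO/AO."""
    header = _vcf_header(contig_lengths, sample)
    obs = sorted(
        observations, key=lambda o: (list(contig_lengths).index(o.scaffold), o.pos)
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for o in obs:
            alt = o.alt_allele if o.alt_allele is not None else "<NON_REF>"
            rec = vcf.new_record(
                contig=o.scaffold, start=o.pos - 1, alleles=(o.ref_allele, alt)
            )
            rec.samples[sample]["GT"] = (None,)
            rec.samples[sample]["DP"] = (
                o.total_depth
                if o.total_depth is not None
                else o.ref_depth + o.alt_depth
            )
            rec.samples[sample]["RO"] = o.ref_depth
            rec.samples[sample]["AO"] = (o.alt_depth,)
            vcf.write(rec)


def _record_depths(rec, sample_values, alt_index: int) -> tuple[int, int]:
    """Extract (RO, AO[alt_index]) from a VCF record, falling back to AD."""
    ro = sample_values.get("RO")
    ao = sample_values.get("AO")
    if ro is not None and ao is not None:
        ao_i = ao[alt_index] if isinstance(ao, (tuple, list)) else ao
        if ro is not None and ao_i is not None:
            return int(ro), int(ao_i)
    ad = sample_values.get("AD")
    if ad is not None and len(ad) > alt_index + 1 and ad[0] is not None:
        return int(ad[0]), int(ad[alt_index + 1])
    raise ValueError(
        f"record {rec.chrom}:{rec.pos} lacks RO/AO and AD depth fields"
    )


def read_vcf(path: str | Path) -> list[SiteObservation]:
    """Read a VCF into SiteObservations.

    Multi-allelic records are decomposed into one observation per alternate
    allele (sharing RO). Non-SNV records are retained — their ``var_length``
    attribute flags them for the dispersion/SNP filters downstream.
    """
    out: list[SiteObservation] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if samples:
                values = dict(rec.samples[samples[0]].items())
            else:
                values = dict(rec.info.items())
            dp = values.get("DP")
            if isinstance(dp, (tuple, list)):
                dp = dp[0]
            for i, alt in enumerate(alts):
                if alt in (None, "<NON_REF>", "*"):
                    alt = None
                try:
                    ro, ao = _record_depths(rec, values, i)
                except ValueError:
                    if alt is None:
                        ro, ao = int(values.get("RO") or 0), 0
                    else:
                        raise
                out.append(
                    SiteObservation(
                        scaffold=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        ref_depth=ro,
                        alt_depth=ao,
                        total_depth=int(dp) if dp is not None else None,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk, 1-based inclusive in memory)


def write_bed(
    intervals_by_scaffold: Mapping[str, Sequence], path: str | Path, name: str | None = None
) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for scaffold, ivals in intervals_by_scaffold.items():
            for start, end in iv.as_interval_array(ivals):
                cols = [scaffold, str(int(start) - 1), str(int(end))]
                if name is not None:
                    cols.append(name)
                fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read BED into 1-based inclusive interval arrays per scaffold."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            scaffold, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            out.setdefault(scaffold, []).append((start0 + 1, end0))
    return {s: iv.as_interval_array(ivals) for s, ivals in out.items()}


# ---------------------------------------------------------------------------
# Coverage profiles


def write_coverage(
    profile: CoverageProfile, lengths: Mapping[str, int], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "scaffold": list(profile.per_scaffold_mean),
            "length": [lengths[s] for s in profile.per_scaffold_mean],
            "mean_depth": list(profile.per_scaffold_mean.values()),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t")
    per_scaffold = dict(zip(df["scaffold"], df["mean_depth"]))
    genome_mean = float(
        (df["mean_depth"] * df["length"]).sum() / df["length"].sum()
    )
    return CoverageProfile(per_scaffold, genome_mean)


# ---------------------------------------------------------------------------
# TSV matrices and tract tables


def write_matrix(
    matrix: np.ndarray | pd.DataFrame,
    path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    """Write a labelled matrix as TSV (NaN rendered as ``NA``)."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        if labels is None:
            raise ValueError("labels required for a bare array")
        df = pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


_TRACT_COLUMNS = [
    "nucleus",
    "scaffold",
    "start",
    "end",
    "n_supporting",
    "own_clade",
    "donor_clade",
    "outer_start",
    "outer_end",
]


def write_tracts(tracts: Sequence, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write recombination tracts as a TSV plus an optional BED companion.

    Tract spans are 1-based inclusive in the TSV and converted to 0-based
    half-open in the BED.
    """
    rows = []
    for t in tracts:
        rows.append(
            {
                "nucleus": t.nucleus,
                "scaffold": t.scaffold,
                "start": t.start,
                "end": t.end,
                "n_supporting": t.n_supporting,
                "own_clade": t.own_clade,
                "donor_clade": t.donor_clade,
                "outer_start": t.outer_start,
                "outer_end": t.outer_end,
            }
        )
    df = pd.DataFrame(rows, columns=_TRACT_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in rows:
                fh.write(
                    f"{r['scaffold']}\t{r['start'] - 1}\t{r['end']}\t"
                    f"{r['nucleus']}:{r['own_clade']}<-{r['donor_clade']}\n"
                )


def read_tracts(tsv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")


def validate_vcf(path: str | Path) -> dict[str, int]:
    """Light validation pass used by ``karyorec io validate``."""
    obs = read_vcf(path)
    n_snv = sum(1 for o in obs if o.is_snv)
    n_no_depth = sum(1 for o in obs if o.ref_depth + o.alt_depth == 0)
    if n_no_depth:
        warnings.warn(f"{n_no_depth} records carry zero informative reads")
    return {"records": len(obs), "snv": n_snv, "non_snv": len(obs) - n_snv}
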