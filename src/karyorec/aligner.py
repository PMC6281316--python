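"""Local-alignment backends for the flanking-sequence single-copy test.

The default backend is a self-contained k-mer seed + ungapped diagonal
extension aligner with Karlin–Altschul e-values: a flank query is matched
against the whole reference on both strands, seed hits are grouped by
diagonal, and each diagonal is scored by the best-scoring ungapped segment
(match +1, mismatch −2).  A "good hit" is a diagonal whose e-value

    E = K * m * n_eff * exp(-lambda * S)

is at or below the configured threshold.  lambda is the positive root of
sum_ij p_i p_j exp(lambda * s_ij) = 1 under uniform base composition; K is
held at 0.35, a standard-order approximation — at the 0.001 threshold with
100 bp flanks the hit/no-hit decision is insensitive to K to within orders
of magnitude.

An optional BLAST+ backend (``blastn``) gives an external cross-check; both
backends expose ``count_hits(query) -> int``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .io import Reference

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

MATCH = 1
MISMATCH = -2
KA_K = 0.35  # order-of-magnitude approximation; see module docstring


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def karlin_lambda(match: int = MATCH, mismatch: int = MISMATCH) -> float:
    """Positive root of 0.25 e^{λ·match} + 0.75 e^{λ·mismatch} = 1."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; positions containing non-ACGT get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        vals = vals * 4 + np.where(window == 4, 0, window).astype(np.int64)
        bad |= window == 4
    vals[bad] = -1
    return vals


def best_ungapped_score(query: np.ndarray, target: np.ndarray) -> int:
    """Best-scoring ungapped local segment between two equal-length code arrays."""
    n = min(len(query), len(target))
    if n == 0:
        return 0
    q, t = query[:n], target[:n]
    s = np.where((q == t) & (q != 4), MATCH, MISMATCH).astype(np.int64)
    cs = np.cumsum(s)
    prefix_min = np.minimum.accumulate(np.concatenate(([0], cs[:-1])))
    return int(np.max(cs - prefix_min))


class KmerAligner:
    """Seed-and-extend local aligner over a whole reference genome."""

    def __init__(self, reference: Reference, k: int = 13):
        self.k = k
        self.lambda_ = karlin_lambda()
        sep = np.full(k, 4, dtype=np.uint8)
        parts: list[np.ndarray] = []
        offset = 0
        self._offsets: dict[str, int] = {}
        for name in reference.names:
            self._offsets[name] = offset
            codes = encode(reference[name])
            parts.append(codes)
            parts.append(sep)
            offset += len(codes) + k
        self.genome = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.n_residues = int((self.genome != 4).sum())
        kmers = _kmer_codes(self.genome, k)
        valid = np.flatnonzero(kmers >= 0)
        order = np.argsort(kmers[valid], kind="stable")
        self._sorted_kmers = kmers[valid][order]
        self._sorted_pos = valid[order]

    def evalue(self, score: int, query_len: int) -> float:
        # both strands are searched, hence the factor 2 in the search space
        space = 2.0 * query_len * max(self.n_residues, 1)
        return float(KA_K * space * np.exp(-self.lambda_ * score))

    def _seed_diagonals(self, qcodes: np.ndarray) -> np.ndarray:
        qk = _kmer_codes(qcodes, self.k)
        qpos = np.flatnonzero(qk >= 0)
        if len(qpos) == 0:
            return np.empty(0, dtype=np.int64)
        codes = qk[qpos]
        lo = np.searchsorted(self._sorted_kmers, codes, side="left")
        hi = np.searchsorted(self._sorted_kmers, codes, side="right")
        diags = []
        for q, a, b in zip(qpos, lo, hi):
            if b > a:
                diags.append(self._sorted_pos[a:b] - q)
        if not diags:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(diags))

    def _strand_hits(self, qcodes: np.ndarray, evalue_max: float) -> int:
        qlen = len(qcodes)
        hits = 0
        for d in self._seed_diagonals(qcodes):
            g0 = int(d)
            g1 = min(g0 + qlen, len(self.genome))
            if g0 < 0:
                target = self.genome[0:g1]
                score = best_ungapped_score(qcodes[-g0:], target)
            else:
                score = best_ungapped_score(qcodes, self.genome[g0:g1])
            if self.evalue(score, qlen) <= evalue_max:
                hits += 1
        return hits

    def count_hits(self, query: str, evalue_max: float = 1e-3) -> int:
        """Number of good local hits of the query in the reference (both strands)."""
        qcodes = encode(query)
        if len(qcodes) < self.k:
            return 0
        return self._strand_hits(qcodes, evalue_max) + self._strand_hits(
            revcomp_codes(qcodes), evalue_max
        )


class BlastAligner:
    """External BLAST+ backend; requires ``makeblastdb``/``blastn`` on PATH."""

    def __init__(self, reference: Reference):
        if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
            raise RuntimeError("BLAST+ (blastn/makeblastdb) not found on PATH")
        self._tmp = tempfile.TemporaryDirectory(prefix="karyorec_blastdb_")
        db_fasta = Path(self._tmp.name) / "ref.fa"
        with open(db_fasta, "w") as fh:
            for name in reference.names:
                fh.write(f">{name}\n{reference[name]}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(db_fasta), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        self._db = str(db_fasta)

    def count_hits(self, query: str, evalue_max: float = 1e-3) -> int:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".fa", dir=self._tmp.name, delete=False
        ) as fh:
            fh.write(f">q\n{query}\n")
            qpath = fh.name
        res = subprocess.run(
            [
                "blastn",
                "-task",
                "blastn",
                "-dust",
                "no",
                "-query",
                qpath,
                "-db",
                self._db,
                "-evalue",
                str(evalue_max),
                "-outfmt",
                "6 evalue",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
        lines = [ln for ln in res.stdout.splitlines() if ln.strip()]
        return sum(1 for ln in lines if float(ln) <= evalue_max)
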