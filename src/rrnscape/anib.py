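"""Fragmentation-based average nucleotide identity (ANIb).

The query genome is cut into consecutive 1000-nt fragments, each fragment is
aligned to the reference, and fragments with a positive match (alignment of
more than 70% of the fragment length and at least 30% nucleotide identity)
contribute their percent identity to the one-way score.  Because one-way
scores are not symmetric, the final score is the mean of the two reciprocal
values.

Two aligners satisfy the same per-fragment contract (best local match with
its identity and aligned fraction): a built-in k-mer seed-and-vote aligner
suited to the generator's substitution-only sequences, and an external
blastn adapter for real data.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np

_CODE = {c: i for i, c in enumerate("ACGT")}


def as_codes(seq) -> np.ndarray:
    """Accept a uint8 code array or an ACGT string."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.zeros(len(arr), dtype=np.uint8)
    for c, i in _CODE.items():
        out[arr == ord(c)] = i
    return out


@dataclass(frozen=True)
class FragmentHit:
    fragment_index: int
    aligned_fraction: float  # % of fragment length
    pct_identity: float


@dataclass(frozen=True)
class AnibResult:
    oneway_ab: Optional[float]
    oneway_ba: Optional[float]
    final: Optional[float]
    n_positive_ab: int
    n_positive_ba: int


def fragment_sequence(seq, size: int = 1000, drop_below: Optional[int] = None) -> list:
    """Non-overlapping consecutive windows; the trailing remainder is kept
    as a short final fragment unless ``drop_below`` discards it."""
    codes = as_codes(seq)
    if len(codes) == 0:
        raise ValueError("empty sequence")
    frags = [codes[i : i + size] for i in range(0, len(codes), size)]
    if drop_below is not None and len(frags[-1]) < drop_below:
        frags = frags[:-1]
    return frags


def positive_match(hit: FragmentHit, min_aln: float = 70.0, min_id: float = 30.0) -> bool:
    """Aligned fraction strictly greater than 70%, identity at least 30%."""
    return hit.aligned_fraction > min_aln and hit.pct_identity >= min_id


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j : j + n]
    return out


class KmerVoteAligner:
    """Seed-and-vote local aligner for substitution-diverged sequences.

    Exact k-mer matches against an indexed reference vote for a diagonal
    offset; the winning offset places the fragment, and identity is the
    column-wise match fraction over the overlap.  Without enough seed votes
    the fragment has no hit (as a word-based aligner would report).
    """

    def __init__(self, reference, k: int = 14, max_hits_per_kmer: int = 16,
                 min_votes: int = 2):
        self.ref = as_codes(reference)
        self.k = k
        self.max_hits = max_hits_per_kmer
        self.min_votes = min_votes
        kmers = _kmer_codes(self.ref, k)
        self._order = np.argsort(kmers, kind="stable")
        self._sorted = kmers[self._order]

    def best_hit(self, fragment: np.ndarray, index: int = 0) -> Optional[FragmentHit]:
        frag = as_codes(fragment)
        if len(frag) < self.k:
            return None
        qk = _kmer_codes(frag, self.k)
        lo = np.searchsorted(self._sorted, qk, side="left")
        hi = np.searchsorted(self._sorted, qk, side="right")
        offsets = []
        for qpos in range(len(qk)):
            a, b = lo[qpos], hi[qpos]
            if b - a == 0 or b - a > self.max_hits:
                continue
            offsets.append(self._order[a:b] - qpos)
        if not offsets:
            return None
        offsets = np.concatenate(offsets)
        vals, counts = np.unique(offsets, return_counts=True)
        best = int(np.argmax(counts))
        if counts[best] < self.min_votes:
            return None
        off = int(vals[best])
        rs, re = max(off, 0), min(off + len(frag), len(self.ref))
        if re <= rs:
            return None
        qs = rs - off
        overlap = re - rs
        matches = int(np.count_nonzero(self.ref[rs:re] == frag[qs : qs + overlap]))
        return FragmentHit(
            fragment_index=index,
            aligned_fraction=100.0 * overlap / len(frag),
            pct_identity=100.0 * matches / overlap,
        )

    def align_fragments(self, fragments) -> List[Optional[FragmentHit]]:
        return [self.best_hit(f, i) for i, f in enumerate(fragments)]


class BlastnAligner:
    """External blastn satisfying the same per-fragment contract."""

    def __init__(self, reference):
        self.ref = as_codes(reference)

    def align_fragments(self, fragments) -> List[Optional[FragmentHit]]:
        from .synthetic_data import codes_to_fasta

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            (tmp / "ref.fa").write_text(codes_to_fasta(self.ref, "ref"))
            with open(tmp / "frags.fa", "w") as fh:
                for i, f in enumerate(fragments):
                    fh.write(codes_to_fasta(as_codes(f), f"frag{i}"))
            subprocess.run(
                ["makeblastdb", "-in", str(tmp / "ref.fa"), "-dbtype", "nucl"],
                check=True,
                capture_output=True,
            )
            res = subprocess.run(
                [
                    "blastn",
                    "-query",
                    str(tmp / "frags.fa"),
                    "-db",
                    str(tmp / "ref.fa"),
                    "-outfmt",
                    "6 qseqid pident length bitscore",
                    "-max_target_seqs",
                    "1",
                ],
                check=True,
                capture_output=True,
                text=True,
            )
        best: dict = {}
        for line in res.stdout.splitlines():
            q, pid, length, score = line.split("\t")
            i = int(q[4:])
            if i not in best or float(score) > best[i][2]:
                best[i] = (float(pid), int(length), float(score))
        out: List[Optional[FragmentHit]] = []
        for i, f in enumerate(fragments):
            if i in best:
                pid, length, _ = best[i]
                out.append(FragmentHit(i, 100.0 * length / len(f), pid))
            else:
                out.append(None)
        return out


def anib_oneway(
    query,
    reference,
    aligner_cls=KmerVoteAligner,
    fragment_size: int = 1000,
    min_aln: float = 70.0,
    min_id: float = 30.0,
    drop_below: Optional[int] = None,
):
    """One-way ANIb: mean identity over positive fragments.

    Returns ``(score, n_positive)``; the score is None when no fragment has
    a positive match.
    """
    frags = fragment_sequence(query, fragment_size, drop_below)
    aligner = aligner_cls(reference)
    identities = []
    for hit in aligner.align_fragments(frags):
        if hit is not None and positive_match(hit, min_aln, min_id):
            identities.append(hit.pct_identity)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def anib(genome_a, genome_b, aligner_cls=KmerVoteAligner, **kw) -> AnibResult:
    """Reciprocal ANIb: the final score averages the two one-way scores."""
    ab, n_ab = anib_oneway(genome_a, genome_b, aligner_cls, **kw)
    ba, n_ba = anib_oneway(genome_b, genome_a, aligner_cls, **kw)
    defined = [v for v in (ab, ba) if v is not None]
    final = float(np.mean(defined)) if defined else None
    return AnibResult(ab, ba, final, n_ab, n_ba)
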