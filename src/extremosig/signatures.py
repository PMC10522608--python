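"""Genomic signatures: representative fragments, canonical k-mer vectors, fCGR grids.

A *genomic signature* is here the strand-symmetrized canonical k-mer
frequency vector of a single 500 kbp DNA fragment chosen to represent a
genome assembly.  Counting is strand-symmetric: a k-mer and its reverse
complement are indistinguishable, and every count is accumulated over both
the fragment and its reverse complement, so ``signature(s) ==
signature(revcomp(s))`` holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ContigSet",
    "RepresentativeFragment",
    "Signature",
    "FCGRGrid",
    "EmptyAssembly",
    "InsufficientSequence",
    "select_fragment",
    "canonical_kmer_list",
    "count_canonical_kmers",
    "fcgr_map",
    "read_assembly_fasta",
    "write_fragment_fasta",
    "plot_fcgr",
    "signatures_from_contigsets",
    "write_signature_matrix",
    "read_signature_matrix",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: uppercase + map IUPAC ambiguity codes (other than N) to N
_AMBIG = "RYSWKMBDHV"
_NORMALIZE = str.maketrans(
    _AMBIG.lower() + _AMBIG + "acgtn", "N" * (2 * len(_AMBIG)) + "ACGTN"
)


class EmptyAssembly(ValueError):
    """Raised when an assembly has no contigs."""


class InsufficientSequence(ValueError):
    """Raised when an assembly has fewer non-N bases than the target fragment length."""


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return s.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    out = seq.translate(_NORMALIZE)
    bad = set(out) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return out


@dataclass
class ContigSet:
    """Ordered DNA contigs of one assembly.

    Sequences are uppercased on ingest; IUPAC ambiguity codes other than N
    are mapped to N (with a logged warning).
    """

    assembly_id: str
    contigs: list[str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise EmptyAssembly(f"assembly {self.assembly_id!r} has no contigs")
        normed = []
        warned = False
        for c in self.contigs:
            n = _normalize(c)
            if not warned and any(ch not in "ACGTN" for ch in set(c.upper())):
                logger.warning(
                    "assembly %s: ambiguity codes mapped to N", self.assembly_id
                )
                warned = True
            normed.append(n)
        self.contigs = normed

    @property
    def total_non_n(self) -> int:
        return sum(len(c) - c.count("N") for c in self.contigs)


@dataclass
class RepresentativeFragment:
    """A 500 kbp (by default) fragment representing one assembly.

    ``effective_length`` counts non-N characters only; inserted N separators
    between concatenated contigs never contribute to it.
    """

    assembly_id: str
    sequence: str
    effective_length: int
    selection_mode: str  # "single-contig-window" | "concatenation"
    seed: int | None = None
    window_offset: int | None = None


def select_fragment(
    contigs: ContigSet, target_len: int = 500_000, seed: int = 0
) -> RepresentativeFragment:
    """Select the representative DNA fragment of an assembly.

    Contigs are sorted by length, longest first (stable for ties).  If the
    longest contig holds at least ``target_len`` non-N bases, a window with a
    uniformly random seeded offset is cut from it; otherwise the sorted
    contigs are concatenated one by one with a single ``N`` separator between
    pieces, the last contig truncated (prefix) so that the non-N length is
    exactly ``target_len``.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if contigs.total_non_n < target_len:
        raise InsufficientSequence(
            f"assembly {contigs.assembly_id!r}: {contigs.total_non_n} non-N bp "
            f"< target {target_len}"
        )
    order = sorted(range(len(contigs.contigs)),
                   key=lambda i: -len(contigs.contigs[i]))
    sorted_contigs = [contigs.contigs[i] for i in order]
    longest = sorted_contigs[0]
    n_longest = len(longest) - longest.count("N")
    if n_longest >= target_len:
        rng = np.random.default_rng(seed)
        offset = int(rng.integers(0, n_longest - target_len + 1))
        if longest.count("N") == 0:
            window = longest[offset:offset + target_len]
        else:
            # offset and span are in non-N coordinates so the fragment always
            # carries exactly target_len informative bases
            non_n_pos = np.flatnonzero(np.frombuffer(
                longest.encode(), dtype=np.uint8) != ord("N"))
            start = non_n_pos[offset]
            end = non_n_pos[offset + target_len - 1] + 1
            window = longest[start:end]
        return RepresentativeFragment(
            assembly_id=contigs.assembly_id,
            sequence=window,
            effective_length=target_len,
            selection_mode="single-contig-window",
            seed=seed,
            window_offset=offset,
        )
    pieces: list[str] = []
    acc = 0
    for c in sorted_contigs:
        non_n = len(c) - c.count("N")
        if acc + non_n < target_len:
            pieces.append(c)
            acc += non_n
            continue
        need = target_len - acc
        if c.count("N") == 0:
            pieces.append(c[:need])
        else:
            non_n_pos = np.flatnonzero(
                np.frombuffer(c.encode(), dtype=np.uint8) != ord("N"))
            pieces.append(c[: non_n_pos[need - 1] + 1])
        acc = target_len
        break
    return RepresentativeFragment(
        assembly_id=contigs.assembly_id,
        sequence="N".join(pieces),
        effective_length=target_len,
        selection_mode="concatenation",
        seed=seed,
    )


@lru_cache(maxsize=None)
def canonical_kmer_list(k: int) -> tuple[str, ...]:
    """Lexicographically sorted canonical k-mers for 1 <= k <= 6.

    For each reverse-complement pair the lexicographically smaller member is
    kept; palindromes (possible only for even k) appear once.  The list has
    4^k/2 entries for odd k and (4^k + 4^(k/2))/2 for even k.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    out = []
    for idx in range(4 ** k):
        kmer = _decode(idx, k)
        if kmer <= revcomp(kmer):
            out.append(kmer)
    return tuple(out)


def _decode(idx: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(chars))


def _encode_seq(sequence: str) -> np.ndarray:
    """Map ACGTN string to codes 0..3, with 4 for N."""
    raw = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    return lut[raw]


@lru_cache(maxsize=None)
def _canonical_maps(k: int):
    """(rc_index, canonical_column, n_canonical) for all 4^k k-mer indices."""
    n = 4 ** k
    digits = np.empty((k, n), dtype=np.int64)
    idx = np.arange(n)
    for j in range(k - 1, -1, -1):
        digits[j] = idx % 4
        idx = idx // 4
    # reverse complement index: complemented digits (3 - d) in reversed order
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        rc += (3 - digits[k - 1 - j]) * (4 ** (k - 1 - j))
    canon_idx = np.minimum(np.arange(n), rc)
    canon_sorted = np.unique(canon_idx)
    col = np.searchsorted(canon_sorted, canon_idx)
    return rc, col, len(canon_sorted)


@dataclass
class Signature:
    """Strand-symmetrized canonical k-mer count/frequency vector."""

    k: int
    kmer_order: tuple[str, ...]
    counts: np.ndarray
    freqs: np.ndarray | None = field(default=None)
    degenerate: bool = False  # no valid window: counts all zero, freqs undefined

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        total = int(self.counts.sum())
        if total > 0:
            self.freqs = self.counts / total
            self.degenerate = False
        else:
            self.freqs = None
            self.degenerate = True

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Signature)
            and self.k == other.k
            and np.array_equal(self.counts, other.counts)
        )

    def full_symmetrized(self) -> np.ndarray:
        """Per-k-mer symmetrized vector over all 4^k k-mers.

        Entry v holds forward-count(v) + forward-count(revcomp(v)); the
        vector sums to 2x the number of valid windows.
        """
        rc, col, _ = _canonical_maps(self.k)
        n = 4 ** self.k
        full = np.empty(n, dtype=np.int64)
        pal = rc == np.arange(n)
        # counts[w] = f2[w] + f2[rc w] for non-palindromes, f2[p] for palindromes
        per = self.counts[col].astype(np.int64)
        full[~pal] = per[~pal] // 2
        full[pal] = per[pal]
        return full


def count_canonical_kmers(sequence: str, k: int) -> Signature:
    """Count canonical k-mers of a DNA-with-N string, strand-symmetrized.

    A sliding window of width k with step 1 is used; windows containing N
    contribute nothing.  Counts accumulate over both the sequence and its
    reverse complement, then reverse-complement pairs are collapsed onto the
    canonical member, so the count total equals 2x the number of valid
    windows and the result is invariant under reverse complementation of the
    input.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    order = canonical_kmer_list(k)
    rc, col, n_canon = _canonical_maps(k)
    codes = _encode_seq(_normalize(sequence))
    if len(codes) < k:
        return Signature(k=k, kmer_order=order, counts=np.zeros(n_canon, np.int64))
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 4).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = win[valid] @ powers
    fwd = np.bincount(idx, minlength=4 ** k).astype(np.int64)
    f2 = fwd + fwd[rc]  # symmetrized per-k-mer vector
    pal = rc == np.arange(4 ** k)
    contrib = np.where(pal, f2, 2 * f2)  # collapsing pairs doubles non-palindromes
    is_canon = np.arange(4 ** k) <= rc
    counts = np.bincount(col, weights=np.where(is_canon, contrib, 0),
                         minlength=n_canon).astype(np.int64)
    return Signature(k=k, kmer_order=order, counts=counts)


@dataclass
class FCGRGrid:
    """2^k x 2^k frequency Chaos Game Representation grid.

    Corner convention: A=(0,0) bottom-left, C=(0,1) top-left, G=(1,1)
    top-right, T=(1,0) bottom-right.  Row 0 of ``grid`` is the TOP row, so
    the cell for k-mer w sits at ``grid[2^k - 1 - y(w), x(w)]``.
    """

    k: int
    grid: np.ndarray
    corner_convention: str = "A=bottom-left,C=top-left,G=top-right,T=bottom-right"


_CORNER_X = {"A": 0, "C": 0, "G": 1, "T": 1}
_CORNER_Y = {"A": 0, "C": 1, "G": 1, "T": 0}


def _pixel(kmer: str) -> tuple[int, int]:
    """(x, y) pixel of a k-mer under the declared corner convention."""
    x = y = 0
    for ch in kmer:
        x = 2 * x + _CORNER_X[ch]
        y = 2 * y + _CORNER_Y[ch]
    return x, y


def fcgr_map(values: Mapping[str, float] | Sequence[float] | np.ndarray,
             k: int) -> FCGRGrid:
    """Place per-k-mer values on the CGR pixel grid.

    ``values`` may be indexed by canonical k-mers (length 4^k/2 or
    (4^k+4^(k/2))/2, or a mapping with canonical keys) — each value is then
    written at both the k-mer's pixel and its reverse complement's pixel — or
    by all 4^k k-mers (one value per pixel).
    """
    side = 2 ** k
    grid = np.zeros((side, side), dtype=float)
    order = canonical_kmer_list(k)
    if isinstance(values, Mapping):
        items = list(values.items())
    else:
        arr = np.asarray(values, dtype=float)
        if arr.shape == (4 ** k,):
            all_kmers = [_decode(i, k) for i in range(4 ** k)]
            items = list(zip(all_kmers, arr))
            for kmer, v in items:
                x, y = _pixel(kmer)
                grid[side - 1 - y, x] = v
            return FCGRGrid(k=k, grid=grid)
        if arr.shape != (len(order),):
            raise ValueError(
                f"expected {len(order)} canonical or {4**k} total values, "
                f"got shape {arr.shape}")
        items = list(zip(order, arr))
    for kmer, v in items:
        if len(kmer) != k:
            raise ValueError(f"k-mer {kmer!r} does not match k={k}")
        for w in {kmer, revcomp(kmer)}:
            x, y = _pixel(w)
            grid[side - 1 - y, x] = v
    return FCGRGrid(k=k, grid=grid)


def plot_fcgr(grid: FCGRGrid, path: str | Path, cmap: str = "Blues") -> None:
    """Render an fCGR grid to an image file (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid.grid, cmap=cmap)
    ax.set_xticks([]); ax.set_yticks([])
    for corner, xy in (("C", (0.02, 0.95)), ("G", (0.93, 0.95)),
                       ("A", (0.02, 0.03)), ("T", (0.93, 0.03))):
        ax.text(*xy, corner, transform=ax.transAxes, fontsize=12)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# I/O helpers


def read_assembly_fasta(path: str | Path, assembly_id: str | None = None) -> ContigSet:
    """Read one multi-record FASTA file as the contigs of one assembly."""
    path = Path(path)
    contigs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return ContigSet(assembly_id=assembly_id or path.stem, contigs=contigs)


def write_fragment_fasta(frag: RepresentativeFragment, path: str | Path) -> None:
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(frag.sequence), id=frag.assembly_id,
                    description=f"mode={frag.selection_mode}")
    SeqIO.write([rec], str(path), "fasta")


def signatures_from_contigsets(
    contigsets: Iterable[ContigSet],
    k: int = 6,
    target_len: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Signature frequency matrix (rows = assemblies, columns = canonical k-mers).

    Each assembly's window offset draws from its own seeded stream derived
    from ``seed`` and the assembly's position, so the matrix is reproducible.
    """
    contigsets = list(contigsets)
    rows, ids = [], []
    ss = np.random.SeedSequence(seed)
    for child, cs in zip(ss.spawn(len(contigsets)), contigsets):
        frag = select_fragment(cs, target_len=target_len,
                               seed=int(child.generate_state(1)[0] % (2 ** 31)))
        sig = count_canonical_kmers(frag.sequence, k)
        if sig.degenerate:
            raise ValueError(f"assembly {cs.assembly_id}: no valid k-mer window")
        rows.append(sig.freqs)
        ids.append(cs.assembly_id)
    return pd.DataFrame(np.vstack(rows), index=ids,
                        columns=list(canonical_kmer_list(k)))


def write_signature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="assembly_id")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="assembly_id")
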