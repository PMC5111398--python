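"""Strict full-length, mismatch-bounded, reference-unique read mapping.

The mapping contract formalises "100% read coverage at 99% identity":

* a hit is an ungapped end-to-end alignment of the whole read against a
  circular reference, on either strand, with at most ``floor(L * (1 -
  identity))`` mismatches (``N`` counts as a mismatch everywhere, on both
  sides);
* a read is ``unique`` when all of its hits fall on a single reference
  (multiple placements within one reference — repeats — still count as
  unique to that species), ``multi_reference`` when hits span two or more
  references, and ``unmapped`` otherwise;
* only unique reads contribute per-base depth, at their best hit (fewest
  mismatches, then smallest start position, then the forward strand).

Candidate generation uses pigeonhole seeding: the read is split into
``m + 1`` equal blocks (``m`` = mismatch budget), so any alignment within
budget contains at least one exact block.  Blocks are located through a
sorted table of modular polynomial hashes of every reference window; hash
collisions can only add candidates (they are removed at verification), never
lose a true hit.  Reverse-strand hits are found by querying the
reverse-complemented read against the forward reference, so reported
positions are always forward-strand 0-based starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._seq import encode, revcomp

__all__ = [
    "ReadAssignment",
    "MappingResult",
    "Index",
    "build_index",
    "map_read",
    "map_reads",
    "brute_force_map",
    "brute_force_map_batch",
]

# hash modulus (prime < 2**26) and multiplier; exactness: 64 blocks * 5 * p < 2**53
_P = 67_108_859
_R = 1_103_515_245 % _P

STATUS_UNIQUE = "unique"
STATUS_MULTI = "multi_reference"
STATUS_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str
    reference_id: str | None = None
    position: int | None = None
    strand: str | None = None
    mismatches: int | None = None


@dataclass
class MappingResult:
    """Per-read assignments plus per-reference per-base depth."""

    assignments: list[ReadAssignment] | None
    depth: dict[str, np.ndarray]
    tallies: dict[str, int] = field(default_factory=dict)
    unique_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(self.tallies.values())


def _as_matrix(reads) -> tuple[np.ndarray, list[str]]:
    """Accept a ReadSet-like object, a (matrix, ids) pair, a list of records,
    or a raw uint8 matrix; return (matrix, ids)."""
    if hasattr(reads, "sequences"):
        mat = reads.sequences
        ids = list(reads.ids) if getattr(reads, "ids", None) is not None else None
    elif isinstance(reads, np.ndarray):
        mat, ids = reads, None
    elif isinstance(reads, (list, tuple)) and reads and hasattr(reads[0], "sequence"):
        mat = np.stack([encode(r.sequence) for r in reads])
        ids = [r.id for r in reads]
    elif isinstance(reads, (list, tuple)) and not reads:
        mat, ids = np.zeros((0, 0), dtype=np.uint8), []
    else:
        raise TypeError(f"unsupported read container: {type(reads)!r}")
    if ids is None:
        ids = [f"read_{i}" for i in range(mat.shape[0])]
    return np.ascontiguousarray(mat, dtype=np.uint8), ids


class Index:
    """Exact-seed index over the forward strand of each circularised reference."""

    def __init__(self, library, read_length: int, max_mismatch_rate: float = 0.01):
        refs = list(library)
        if not refs:
            raise ValueError("reference library is empty")
        if read_length < 2:
            raise ValueError("read_length must be >= 2")
        self.read_length = int(read_length)
        self.max_mismatch_rate = float(max_mismatch_rate)
        budget = int(np.floor(read_length * max_mismatch_rate))
        self.seed_len = read_length // (budget + 1)
        if self.seed_len < 8:
            raise ValueError(
                f"read_length {read_length} too short to support "
                f"{budget + 1} pigeonhole seed blocks of usable length"
            )
        self.ref_ids: list[str] = []
        self.ref_lengths: np.ndarray
        encoded: list[np.ndarray] = []
        for ref in refs:
            rid = getattr(ref, "species_id", None) or getattr(ref, "id")
            seq = getattr(ref, "sequence")
            arr = seq if isinstance(seq, np.ndarray) else encode(seq)
            if arr.size == 0:
                raise ValueError(f"reference {rid!r} is empty")
            self.ref_ids.append(rid)
            encoded.append(np.asarray(arr, dtype=np.uint8))
        self.ref_lengths = np.array([a.size for a in encoded], dtype=np.int64)
        # circular wrap extension for full-length verification
        wrap = self.read_length - 1
        ext = [np.concatenate([a, a[: min(wrap, a.size)]]) for a in encoded]
        self.offsets = np.concatenate([[0], np.cumsum([e.size for e in ext])])[:-1]
        self.bigref = np.concatenate(ext).astype(np.uint8)
        self._encoded = encoded

        self._powers = np.empty(self.seed_len, dtype=np.float64)
        v = 1
        for i in range(self.seed_len):
            self._powers[i] = v
            v = (v * _R) % _P

        hashes, ref_idx, pos = [], [], []
        for k, arr in enumerate(encoded):
            L = arr.size
            if L < self.seed_len:
                continue
            circ = np.concatenate([arr, arr[: self.seed_len - 1]])
            win = np.lib.stride_tricks.sliding_window_view(circ, self.seed_len)[:L]
            h = (win.astype(np.float64) @ self._powers) % _P
            hashes.append(h.astype(np.int64))
            ref_idx.append(np.full(L, k, dtype=np.int32))
            pos.append(np.arange(L, dtype=np.int32))
        h = np.concatenate(hashes)
        order = np.argsort(h, kind="stable")
        self._h_sorted = h[order]
        self._entry_ref = np.concatenate(ref_idx)[order]
        self._entry_pos = np.concatenate(pos)[order]
        self._filter = np.zeros(_P, dtype=bool)
        self._filter[self._h_sorted] = True

    # -- candidate generation -------------------------------------------------

    def _lookup(self, h: np.ndarray):
        """Hash values -> (query row, index entry) candidate pairs."""
        rows = np.nonzero(self._filter[h])[0]
        if rows.size == 0:
            empty = np.zeros(0, dtype=np.int64)
            return empty, empty
        hs = h[rows]
        lo = np.searchsorted(self._h_sorted, hs, side="left")
        hi = np.searchsorted(self._h_sorted, hs, side="right")
        counts = hi - lo
        row_rep = np.repeat(rows, counts)
        idx = np.repeat(lo - np.concatenate([[0], np.cumsum(counts)[:-1]]),
                        counts) + np.arange(row_rep.size)
        return row_rep, idx

    def map_batch(self, mat: np.ndarray, chunk_rows: int = 262_144) -> dict[str, np.ndarray]:
        """Map a (n, L) encoded read matrix.

        Returns arrays: status (0 unmapped, 1 unique, 2 multi), ref, pos,
        strand (0 '+', 1 '-'), mm; best-hit fields are -1 where not unique.
        """
        n, L = mat.shape
        out = {
            "status": np.zeros(n, dtype=np.int8),
            "ref": np.full(n, -1, dtype=np.int32),
            "pos": np.full(n, -1, dtype=np.int64),
            "strand": np.full(n, -1, dtype=np.int8),
            "mm": np.full(n, -1, dtype=np.int32),
        }
        if n == 0:
            return out
        budget = int(np.floor(L * self.max_mismatch_rate))
        n_blocks = budget + 1
        if n_blocks * self.seed_len > L:
            return self._map_batch_scan(mat, budget, out)
        for lo_row in range(0, n, chunk_rows):
            sub = mat[lo_row : lo_row + chunk_rows]
            self._map_chunk(sub, out, lo_row, budget, n_blocks)
        return out

    def _map_chunk(self, mat, out, row_base: int, budget: int, n_blocks: int) -> None:
        n, L = mat.shape
        s = self.seed_len
        F = mat.astype(np.float64)
        powf = self._powers
        powr = powf[::-1]
        S3 = 3.0 * powf.sum()
        cand = []
        for j in range(n_blocks):
            # forward-strand block hash
            h = ((F[:, j * s : (j + 1) * s] @ powf) % _P).astype(np.int64)
            row, idx = self._lookup(h)
            if row.size:
                cand.append((row, idx, j, 0))
            # reverse-strand block hash, computed algebraically from the
            # forward bases: block j of revcomp(read) reads the complement of
            # read[L-(j+1)s : L-js] backwards
            h = ((S3 - F[:, L - (j + 1) * s : L - j * s] @ powr) % _P).astype(np.int64)
            row, idx = self._lookup(h)
            if row.size:
                cand.append((row, idx, j, 1))
        if not cand:
            return
        row = np.concatenate([c[0] for c in cand])
        idx = np.concatenate([c[1] for c in cand])
        ref = self._entry_ref[idx].astype(np.int64)
        start = self._entry_pos[idx].astype(np.int64)
        start -= np.concatenate([np.full(c[0].size, c[2] * s, dtype=np.int64) for c in cand])
        strand = np.concatenate([np.full(c[0].size, c[3], dtype=np.int64) for c in cand])
        reflen = self.ref_lengths[ref]
        keep = reflen >= L  # a read longer than reference + wrap stays unmapped
        row, ref, start, strand, reflen = row[keep], ref[keep], start[keep], strand[keep], reflen[keep]
        if row.size == 0:
            return
        start %= reflen
        # dedupe candidates found via several blocks
        maxL = int(self.ref_lengths.max())
        packed = ((row * len(self.ref_ids) + ref) * maxL + start) * 2 + strand
        packed, uidx = np.unique(packed, return_index=True)
        row, ref, start, strand = row[uidx], ref[uidx], start[uidx], strand[uidx]

        # verify candidates against the wrap-extended references
        gidx = (self.offsets[ref][:, None] + start[:, None] + np.arange(L)[None, :])
        win = self.bigref[gidx]
        qmat = np.empty_like(win)
        fwd_rows = strand == 0
        qmat[fwd_rows] = mat[row[fwd_rows]]
        rev_rows = ~fwd_rows
        if rev_rows.any():
            qmat[rev_rows] = revcomp(mat[row[rev_rows]])
        mm = ((win != qmat) | (win > 3) | (qmat > 3)).sum(axis=1)
        ok = mm <= budget
        row, ref, start, strand, mm = row[ok], ref[ok], start[ok], strand[ok], mm[ok]
        if row.size == 0:
            return
        self._resolve(out, row, ref, start, strand, mm, row_base)

    def _map_batch_scan(self, mat: np.ndarray, budget: int, out: dict) -> dict:
        # fallback for reads too short for the index's seed regime
        hits = _exhaustive_hits(mat, self._encoded, budget)
        if hits[0].size:
            self._resolve(out, *hits, 0)
        return out

    def _resolve(self, out, row, ref, start, strand, mm, row_base: int) -> None:
        """Reduce verified hits to per-read status and best hit."""
        # distinct references per read
        pair = row * len(self.ref_ids) + ref
        upair = np.unique(pair)
        uread = upair // len(self.ref_ids)
        r_first, nref = np.unique(uread, return_counts=True)
        status = np.where(nref >= 2, 2, 1).astype(np.int8)
        out["status"][r_first + row_base] = status
        # best hit for unique reads: (mm, start, strand) lexicographic
        order = np.lexsort((strand, start, mm, row))
        row_s = row[order]
        first = np.ones(row_s.size, dtype=bool)
        first[1:] = row_s[1:] != row_s[:-1]
        sel = order[first]
        uniq_mask = out["status"][row[sel] + row_base] == 1
        sel = sel[uniq_mask]
        out["ref"][row[sel] + row_base] = ref[sel]
        out["pos"][row[sel] + row_base] = start[sel]
        out["strand"][row[sel] + row_base] = strand[sel]
        out["mm"][row[sel] + row_base] = mm[sel]


def build_index(library, read_length: int, max_mismatch_rate: float = 0.01) -> Index:
    """Build the pigeonhole seed index for a reference library."""
    return Index(library, read_length, max_mismatch_rate)


def _assignment_from_arrays(rid: str, res: dict, i: int, index: Index) -> ReadAssignment:
    st = int(res["status"][i])
    if st == 1:
        return ReadAssignment(
            rid,
            STATUS_UNIQUE,
            index.ref_ids[int(res["ref"][i])],
            int(res["pos"][i]),
            "+" if res["strand"][i] == 0 else "-",
            int(res["mm"][i]),
        )
    return ReadAssignment(rid, STATUS_MULTI if st == 2 else STATUS_UNMAPPED)


def map_read(read, index: Index) -> ReadAssignment:
    """Map a single read (SequenceRecord or string)."""
    if isinstance(read, str):
        rid, arr = "read_0", encode(read)
    else:
        rid, arr = read.id, encode(read.sequence)
    res = index.map_batch(arr[None, :])
    return _assignment_from_arrays(rid, res, 0, index)


def _iter_chunks(reads) -> Iterator:
    if hasattr(reads, "sequences") or isinstance(reads, np.ndarray):
        yield reads
    elif isinstance(reads, (list, tuple)) and (not reads or hasattr(reads[0], "sequence")):
        yield reads
    else:
        yield from reads  # iterable of chunks


def map_reads(reads, index: Index, keep_assignments: bool = True) -> MappingResult:
    """Map a read set (or an iterable of read-set chunks) and accumulate depth.

    Depth is incremented only for unique assignments, at the best hit, with
    circular wrap.  Assignment order follows read order.
    """
    wrap = index.read_length  # depth diff-buffer headroom
    diff = {rid: np.zeros(int(L) + 2 * wrap + 1, dtype=np.int64)
            for rid, L in zip(index.ref_ids, index.ref_lengths)}
    assignments: list[ReadAssignment] | None = [] if keep_assignments else None
    tallies = {STATUS_UNIQUE: 0, STATUS_MULTI: 0, STATUS_UNMAPPED: 0}
    unique_counts = {rid: 0 for rid in index.ref_ids}

    for chunk in _iter_chunks(reads):
        mat, ids = _as_matrix(chunk)
        if mat.shape[0] == 0:
            continue
        res = index.map_batch(mat)
        st = res["status"]
        tallies[STATUS_UNMAPPED] += int((st == 0).sum())
        tallies[STATUS_UNIQUE] += int((st == 1).sum())
        tallies[STATUS_MULTI] += int((st == 2).sum())
        L = mat.shape[1]
        uniq = np.nonzero(st == 1)[0]
        for k in np.unique(res["ref"][uniq]):
            rid = index.ref_ids[int(k)]
            starts = res["pos"][uniq[res["ref"][uniq] == k]]
            unique_counts[rid] += starts.size
            d = diff[rid]
            np.add.at(d, starts, 1)
            np.add.at(d, starts + L, -1)
        if assignments is not None:
            for i in range(mat.shape[0]):
                assignments.append(_assignment_from_arrays(ids[i], res, i, index))

    depth: dict[str, np.ndarray] = {}
    for rid, L in zip(index.ref_ids, index.ref_lengths):
        L = int(L)
        d = np.cumsum(diff[rid][:-1])
        folded = d[:L].copy()
        extra = d[L:]  # coverage past the circle end: reads spanning the origin
        if extra.size:  # read length < reference length, so at most one wrap
            folded[: extra.size] += extra
        depth[rid] = folded
    return MappingResult(assignments, depth, tallies, unique_counts)


# -- exhaustive oracle --------------------------------------------------------


def _exhaustive_hits(mat: np.ndarray, encoded: Sequence[np.ndarray], budget: int):
    """All full-length hits of every read against every reference window, by
    dense one-hot Hamming distance (no seeding, no hashing)."""
    n, L = mat.shape
    rows, refs, starts, strands, mms = [], [], [], [], []
    rc = np.ascontiguousarray(revcomp(mat))
    onehot_f = [(mat == b).astype(np.float32) for b in range(4)]
    onehot_r = [(rc == b).astype(np.float32) for b in range(4)]
    for k, arr in enumerate(encoded):
        Lr = arr.size
        if Lr < L:
            continue
        circ = np.concatenate([arr, arr[: L - 1]])
        win = np.lib.stride_tricks.sliding_window_view(circ, L)[:Lr]
        wh = [(win == b).astype(np.float32) for b in range(4)]
        for strand, oh in ((0, onehot_f), (1, onehot_r)):
            matches = np.zeros((n, Lr), dtype=np.float32)
            for b in range(4):
                matches += oh[b] @ wh[b].T
            mm = L - matches.astype(np.int64)
            r, s = np.nonzero(mm <= budget)
            rows.append(r)
            refs.append(np.full(r.size, k, dtype=np.int64))
            starts.append(s.astype(np.int64))
            strands.append(np.full(r.size, strand, dtype=np.int64))
            mms.append(mm[r, s])
    if not rows:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, z, z
    return (np.concatenate(rows), np.concatenate(refs), np.concatenate(starts),
            np.concatenate(strands), np.concatenate(mms))


def brute_force_map_batch(reads, library, max_mismatch_rate: float = 0.01) -> list[ReadAssignment]:
    """Exhaustive-scan oracle with the same contract as :func:`map_reads`.

    Small instances only: cost is O(n_reads * total_reference_length * L).
    """
    mat, ids = _as_matrix(reads)
    ref_ids, encoded = [], []
    for ref in library:
        rid = getattr(ref, "species_id", None) or getattr(ref, "id")
        seq = getattr(ref, "sequence")
        ref_ids.append(rid)
        encoded.append(seq if isinstance(seq, np.ndarray) else encode(seq))
    n, L = mat.shape
    budget = int(np.floor(L * max_mismatch_rate))
    row, ref, start, strand, mm = _exhaustive_hits(mat, encoded, budget)
    out: list[ReadAssignment] = []
    order = np.lexsort((strand, start, mm, ref, row))
    hits_by_read: dict[int, list] = {}
    for idx in order:
        hits_by_read.setdefault(int(row[idx]), []).append(idx)
    for i in range(n):
        hits = hits_by_read.get(i)
        if not hits:
            out.append(ReadAssignment(ids[i], STATUS_UNMAPPED))
            continue
        refs_hit = {int(ref[h]) for h in hits}
        if len(refs_hit) > 1:
            out.append(ReadAssignment(ids[i], STATUS_MULTI))
            continue
        best = min(hits, key=lambda h: (mm[h], start[h], strand[h]))
        out.append(
            ReadAssignment(ids[i], STATUS_UNIQUE, ref_ids[int(ref[best])],
                           int(start[best]), "+" if strand[best] == 0 else "-", int(mm[best]))
        )
    return out


def brute_force_map(read, library, max_mismatch_rate: float = 0.01) -> ReadAssignment:
    """Single-read exhaustive oracle (same contract as :func:`map_read`)."""
    if isinstance(read, str):
        reads = [type("R", (), {"id": "read_0", "sequence": read})()]
    else:
        reads = [read]
    return brute_force_map_batch(reads, library, max_mismatch_rate)[0]
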