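"""Synaptic-weight memory arrangements with exact storage and access accounting.

A digital neuromorphic core stores the weights between M pre-synaptic and N
post-synaptic neurons in one of four table layouts:

``crossbar``
    A dense M x N weight table (WT).  Every pre/post pair has a slot; one of
    the 2**W weight codes is reserved to mark a nonexistent connection, so no
    adjacency table is needed.
``csr``
    Pointer-based compressed sparse row.  WT holds (post address, weight)
    pairs for existent connections only; a pointer table (PT) holds the start
    offset of each pre-synaptic row (plus a final boundary entry).
``rle``
    Pointer-based run-length encoding.  Each WT record carries a run bit:
    0 = the record is a weight, 1 = the record is a run length counting
    consecutive nonexistent post-synaptic targets to skip.
``bmp``
    Pointer-based bitmap.  A dense M x N binary adjacency table (AT) encodes
    existence; WT holds the weights of existent connections, located by
    walking the AT row while advancing a pointer that starts at PT(j).

The access-cost model is abstract: every read or write of a single table
position costs one unit, and the :class:`AccessCounter` on each store records
exactly how many AT/PT/WT positions a traversal touched.  Storage costs count
the bits of the tables actually built, under declared field widths.

Indexing is 0-based throughout (pre rows j in [0, M), post columns i in
[0, N)); pointer-table offsets are 0-based as well.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .cost_model import CostBreakdown

FORMATS = ("crossbar", "csr", "rle", "bmp")

__all__ = [
    "FORMATS",
    "AccessCounter",
    "Synapse",
    "DenseConnectivity",
    "SynapticStore",
    "CrossbarStore",
    "CSRStore",
    "RLEStore",
    "BitmapStore",
    "build_store",
    "pointer_bits",
]


def pointer_bits(n_entries: int) -> int:
    """Width in bits of a pointer addressing ``n_entries`` table positions.

    Zero entries need no pointer (0 bits); otherwise at least one bit.
    """
    if n_entries <= 0:
        return 0
    return max(1, math.ceil(math.log2(n_entries)))


def _address_bits(n: int) -> int:
    # bits to name one of n post-synaptic neurons; a single neuron needs none
    return math.ceil(math.log2(n)) if n > 1 else 0


@dataclass
class AccessCounter:
    """Running tally of single-position memory accesses, one unit each."""

    reads_at: int = 0
    reads_pt: int = 0
    reads_wt: int = 0
    writes_wt: int = 0

    def reset(self) -> None:
        self.reads_at = self.reads_pt = self.reads_wt = self.writes_wt = 0

    def copy(self) -> "AccessCounter":
        return AccessCounter(self.reads_at, self.reads_pt, self.reads_wt, self.writes_wt)

    @property
    def total_reads(self) -> int:
        return self.reads_at + self.reads_pt + self.reads_wt

    def __sub__(self, other: "AccessCounter") -> "AccessCounter":
        return AccessCounter(
            self.reads_at - other.reads_at,
            self.reads_pt - other.reads_pt,
            self.reads_wt - other.reads_wt,
            self.writes_wt - other.writes_wt,
        )

    def as_dict(self) -> dict:
        return {
            "reads_at": self.reads_at,
            "reads_pt": self.reads_pt,
            "reads_wt": self.reads_wt,
            "writes_wt": self.writes_wt,
        }


@dataclass(frozen=True)
class Synapse:
    """One existent connection: (pre index, post index, weight)."""

    pre: int
    post: int
    weight: float


class DenseConnectivity:
    """Dense M x N adjacency + weight description of a network.

    ``exists[j, i]`` flags the connection from pre-synaptic neuron j to
    post-synaptic neuron i; ``weight[j, i]`` is ignored wherever
    ``exists`` is False.
    """

    def __init__(self, exists: np.ndarray, weight: np.ndarray):
        exists = np.asarray(exists, dtype=bool)
        weight = np.asarray(weight, dtype=float)
        if exists.ndim != 2:
            raise ValueError("exists must be a 2-D adjacency matrix")
        if exists.shape != weight.shape:
            raise ValueError("exists and weight shapes differ")
        if exists.shape[0] < 1 or exists.shape[1] < 1:
            raise ValueError("M and N must both be at least 1")
        if not np.all(np.isfinite(weight[exists])):
            raise ValueError("weights of existent connections must be finite")
        self.exists = exists
        self.weight = np.where(exists, weight, 0.0)

    @property
    def M(self) -> int:
        return self.exists.shape[0]

    @property
    def N(self) -> int:
        return self.exists.shape[1]

    @property
    def n_connections(self) -> int:
        return int(self.exists.sum())

    @property
    def density(self) -> float:
        return self.n_connections / (self.M * self.N)

    @classmethod
    def from_entries(cls, M: int, N: int, entries) -> "DenseConnectivity":
        """Build from a list of (pre, post, weight) triples."""
        exists = np.zeros((M, N), dtype=bool)
        weight = np.zeros((M, N), dtype=float)
        for pre, post, w in entries:
            exists[pre, post] = True
            weight[pre, post] = w
        return cls(exists, weight)

    def entries(self) -> list:
        js, iis = np.nonzero(self.exists)
        return [[int(j), int(i), float(self.weight[j, i])] for j, i in zip(js, iis)]

    def to_json(self) -> str:
        return json.dumps({"M": self.M, "N": self.N, "entries": self.entries()})

    @classmethod
    def from_json(cls, text: str) -> "DenseConnectivity":
        obj = json.loads(text)
        return cls.from_entries(obj["M"], obj["N"], obj["entries"])

    def to_csv(self, weight_path, adjacency_path) -> None:
        np.savetxt(weight_path, self.weight, delimiter=",")
        np.savetxt(adjacency_path, self.exists.astype(int), delimiter=",", fmt="%d")

    @classmethod
    def from_csv(cls, weight_path, adjacency_path) -> "DenseConnectivity":
        weight = np.loadtxt(weight_path, delimiter=",", ndmin=2)
        exists = np.loadtxt(adjacency_path, delimiter=",", ndmin=2).astype(bool)
        return cls(exists, weight)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DenseConnectivity)
            and np.array_equal(self.exists, other.exists)
            and np.array_equal(self.weight, other.weight)
        )


class SynapticStore:
    """Contract shared by the four concrete memory arrangements.

    Subclasses implement the structural walks; every counted operation
    increments :attr:`counters` by the number of table positions the walk
    touches under the one-packet-per-access model.
    """

    format_tag: str = "abstract"

    def __init__(self, M: int, N: int):
        if M < 1 or N < 1:
            raise ValueError("M and N must both be at least 1")
        self.M = M
        self.N = N
        self.counters = AccessCounter()

    # -- structural helpers (no accounting) ---------------------------------
    def row_posts(self, j: int) -> np.ndarray:
        """Post indices of row j, ascending (structure only, not counted)."""
        raise NotImplementedError

    def row_count(self, j: int) -> int:
        return len(self.row_posts(j))

    @property
    def n_connections(self) -> int:
        raise NotImplementedError

    def _check_pre(self, j: int) -> None:
        if not 0 <= j < self.M:
            raise IndexError(f"pre index {j} out of range [0, {self.M})")

    def _check_post(self, i: int) -> None:
        if not 0 <= i < self.N:
            raise IndexError(f"post index {i} out of range [0, {self.N})")

    # -- counted operations -------------------------------------------------
    def charge_forward(self, j: int) -> None:
        """Account one forward traversal of row j without materialising it."""
        raise NotImplementedError

    def forward_synapses(self, j: int) -> list:
        """Existent synapses of pre neuron j, ascending post order (counted)."""
        raise NotImplementedError

    def reverse_synapses(self, i: int) -> list:
        """Incoming synapses of post neuron i, ascending pre order (counted)."""
        raise NotImplementedError

    def get_weight(self, j: int, i: int) -> float:
        raise NotImplementedError

    def set_weight(self, j: int, i: int, value: float) -> None:
        raise NotImplementedError

    # -- engine fast path (counted in bulk, same totals as the walks) -------
    def read_row(self, j: int) -> np.ndarray:
        """Weights of row j aligned with :meth:`row_posts`; charges one
        forward traversal."""
        self.charge_forward(j)
        return self._row_weights(j).copy()

    def _row_weights(self, j: int) -> np.ndarray:
        raise NotImplementedError

    def add_row(self, j: int, local_idx: np.ndarray, deltas: np.ndarray) -> None:
        """In-place ``w[row j][local_idx] += deltas``; one WT write each."""
        raise NotImplementedError

    def read_col(self, i: int):
        """(pre indices, weights) of column i; charges one reverse traversal."""
        raise NotImplementedError

    def add_col(self, i: int, pres: np.ndarray, deltas: np.ndarray) -> None:
        raise NotImplementedError

    # -- storage ------------------------------------------------------------
    def storage_bits(self, weight_bits: int) -> CostBreakdown:
        """Bits used by the built tables with W-bit weight fields."""
        raise NotImplementedError

    def to_dense(self) -> DenseConnectivity:
        exists = np.zeros((self.M, self.N), dtype=bool)
        weight = np.zeros((self.M, self.N), dtype=float)
        for j in range(self.M):
            posts = self.row_posts(j)
            exists[j, posts] = True
            weight[j, posts] = self._row_weights(j)
        return DenseConnectivity(exists, weight)

    def dump_tables(self) -> dict:
        """JSON-serialisable dump of the encoded tables (golden-file tests)."""
        raise NotImplementedError


class CrossbarStore(SynapticStore):
    """Dense M x N weight table; nonexistence is a reserved weight code.

    Weights are kept as floats at run time; the reserved all-zeros code only
    enters the storage model (`storage_bits`), mirroring the separation
    between the accounting abstraction and physical storage.
    """

    format_tag = "crossbar"

    def __init__(self, dense: DenseConnectivity):
        super().__init__(dense.M, dense.N)
        self.exists = dense.exists.copy()
        self.wt = dense.weight.copy()
        self._posts = [np.nonzero(self.exists[j])[0] for j in range(self.M)]

    @property
    def n_connections(self) -> int:
        return int(self.exists.sum())

    def row_posts(self, j: int) -> np.ndarray:
        self._check_pre(j)
        return self._posts[j]

    def charge_forward(self, j: int) -> None:
        self._check_pre(j)
        self.counters.reads_wt += self.N

    def forward_synapses(self, j: int) -> list:
        self.charge_forward(j)
        return [Synapse(j, int(i), float(self.wt[j, i])) for i in self.row_posts(j)]

    def reverse_synapses(self, i: int) -> list:
        self._check_post(i)
        # transposed indexing: read the full column, M WT positions
        self.counters.reads_wt += self.M
        pres = np.nonzero(self.exists[:, i])[0]
        return [Synapse(int(j), i, float(self.wt[j, i])) for j in pres]

    def get_weight(self, j: int, i: int) -> float:
        self._check_pre(j)
        self._check_post(i)
        if not self.exists[j, i]:
            raise ValueError(f"connection ({j}, {i}) does not exist")
        self.counters.reads_wt += 1  # direct addressing
        return float(self.wt[j, i])

    def set_weight(self, j: int, i: int, value: float) -> None:
        self._check_pre(j)
        self._check_post(i)
        if not self.exists[j, i]:
            raise ValueError(f"connection ({j}, {i}) does not exist")
        self.wt[j, i] = value
        self.counters.writes_wt += 1

    def _row_weights(self, j: int) -> np.ndarray:
        return self.wt[j, self._posts[j]]

    def add_row(self, j: int, local_idx: np.ndarray, deltas: np.ndarray) -> None:
        self.wt[j, self._posts[j][local_idx]] += deltas
        self.counters.writes_wt += len(local_idx)

    def read_col(self, i: int):
        self.counters.reads_wt += self.M
        pres = np.nonzero(self.exists[:, i])[0]
        return pres, self.wt[pres, i].copy()

    def add_col(self, i: int, pres: np.ndarray, deltas: np.ndarray) -> None:
        self.wt[pres, i] += deltas
        self.counters.writes_wt += len(pres)

    def storage_bits(self, weight_bits: int) -> CostBreakdown:
        return CostBreakdown(0, 0, self.M * self.N * weight_bits)

    def dump_tables(self) -> dict:
        return {
            "format": self.format_tag,
            "WT": [[float(w) if e else None for w, e in zip(wr, er)]
                   for wr, er in zip(self.wt, self.exists)],
        }


class _PointerStore(SynapticStore):
    """Shared backing for the pointer-based formats: a flat row-major weight
    list plus per-format encoded metadata."""

    def __init__(self, dense: DenseConnectivity):
        super().__init__(dense.M, dense.N)
        csr = sparse.csr_matrix(
            (dense.weight[dense.exists],
             np.nonzero(dense.exists)[1],
             np.concatenate([[0], np.cumsum(dense.exists.sum(axis=1))])),
            shape=(dense.M, dense.N),
        )
        self.indptr = csr.indptr.astype(np.int64)
        self.indices = csr.indices.astype(np.int64)
        self.data = csr.data.astype(float)

    @property
    def n_connections(self) -> int:
        return len(self.data)

    def row_posts(self, j: int) -> np.ndarray:
        self._check_pre(j)
        return self.indices[self.indptr[j]:self.indptr[j + 1]]

    def _row_weights(self, j: int) -> np.ndarray:
        return self.data[self.indptr[j]:self.indptr[j + 1]]

    def add_row(self, j: int, local_idx: np.ndarray, deltas: np.ndarray) -> None:
        self.data[self.indptr[j] + np.asarray(local_idx)] += deltas
        self.counters.writes_wt += len(local_idx)

    def _locate(self, j: int, i: int) -> int:
        """Flat WT position of connection (j, i); raises if nonexistent."""
        self._check_pre(j)
        self._check_post(i)
        posts = self.row_posts(j)
        pos = int(np.searchsorted(posts, i))
        if pos == len(posts) or posts[pos] != i:
            raise ValueError(f"connection ({j}, {i}) does not exist")
        return int(self.indptr[j]) + pos

    def set_weight(self, j: int, i: int, value: float) -> None:
        flat = self._locate(j, i)
        self._charge_locate(j, i)
        self.data[flat] = value
        self.counters.writes_wt += 1

    def get_weight(self, j: int, i: int) -> float:
        flat = self._locate(j, i)
        self._charge_locate(j, i)  # reads up to and including the weight
        return float(self.data[flat])

    def _charge_locate(self, j: int, i: int) -> None:
        """Accounting of locating connection (j, i) by forward traversal."""
        raise NotImplementedError


class CSRStore(_PointerStore):
    """Pointer-based compressed sparse row.

    WT holds (post address, weight) pairs of existent connections, row-major;
    PT holds M+1 offsets (the extra boundary entry gives every row a stop
    pointer; the storage model charges the M pointers of the printed
    accounting, the boundary entry is charged to neither table).
    """

    format_tag = "csr"

    def charge_forward(self, j: int) -> None:
        self._check_pre(j)
        self.counters.reads_pt += 2  # start and stop pointers
        self.counters.reads_wt += int(self.indptr[j + 1] - self.indptr[j])

    def forward_synapses(self, j: int) -> list:
        self.charge_forward(j)
        return [Synapse(j, int(i), float(w))
                for i, w in zip(self.row_posts(j), self._row_weights(j))]

    def reverse_synapses(self, i: int) -> list:
        self._check_post(i)
        # full sweep: every boundary pointer once, every WT entry once
        self.counters.reads_pt += self.M + 1
        self.counters.reads_wt += len(self.data)
        out = []
        for j in range(self.M):
            for i2, w in zip(self.row_posts(j), self._row_weights(j)):
                if i2 == i:
                    out.append(Synapse(j, i, float(w)))
        return out

    def _charge_locate(self, j: int, i: int) -> None:
        posts = self.row_posts(j)
        pos = int(np.searchsorted(posts, i)) + 1  # entries read up to and incl. i
        self.counters.reads_pt += 2
        self.counters.reads_wt += pos

    def read_col(self, i: int):
        self.counters.reads_pt += self.M + 1
        self.counters.reads_wt += len(self.data)
        mask = self.indices == i
        pres = np.searchsorted(self.indptr, np.nonzero(mask)[0], side="right") - 1
        return pres.astype(np.int64), self.data[mask].copy()

    def add_col(self, i: int, pres: np.ndarray, deltas: np.ndarray) -> None:
        for j, d in zip(pres, deltas):
            self.data[self._locate(j, int(i))] += d
        self.counters.writes_wt += len(pres)

    def storage_bits(self, weight_bits: int) -> CostBreakdown:
        nnz = self.n_connections
        wt = nnz * (_address_bits(self.N) + weight_bits)
        pt = self.M * pointer_bits(nnz)
        return CostBreakdown(0, pt, wt)

    def dump_tables(self) -> dict:
        return {
            "format": self.format_tag,
            "PT": [int(p) for p in self.indptr],
            "WT": [[int(i), float(w)] for i, w in zip(self.indices, self.data)],
        }


class RLEStore(_PointerStore):
    """Pointer-based run-length encoding.

    Each row is a record list: a weight record (run bit 0) carries the next
    existent connection's weight; a run record (run bit 1) carries a count of
    consecutive nonexistent post targets to skip.  Runs are merged maximally
    and trailing runs are not emitted, so a row holds at most 2*k_j records.
    """

    format_tag = "rle"

    def __init__(self, dense: DenseConnectivity):
        super().__init__(dense)
        # records per row: (is_run, value); weight records store flat WT index
        self.row_records: list = []
        flat = 0
        for j in range(dense.M):
            posts = self.indices[self.indptr[j]:self.indptr[j + 1]]
            recs = []
            cursor = 0
            for i in posts:
                gap = int(i) - cursor
                if gap > 0:
                    if gap > dense.N:
                        raise ValueError("RLE run exceeds row length")
                    recs.append((True, gap))
                recs.append((False, flat))
                flat += 1
                cursor = int(i) + 1
            self.row_records.append(recs)
        self.n_run_records = sum(int(is_run) for recs in self.row_records for is_run, _ in recs)
        self.n_weight_records = self.n_connections
        self.n_records = self.n_run_records + self.n_weight_records

    def _row_record_count(self, j: int) -> int:
        return len(self.row_records[j])

    def charge_forward(self, j: int) -> None:
        self._check_pre(j)
        self.counters.reads_pt += 1
        self.counters.reads_wt += self._row_record_count(j)

    def forward_synapses(self, j: int) -> list:
        self.charge_forward(j)
        out = []
        cursor = 0
        for is_run, value in self.row_records[j]:
            if is_run:
                cursor += value
            else:
                out.append(Synapse(j, cursor, float(self.data[value])))
                cursor += 1
        if cursor > self.N:
            raise ValueError("RLE row decodes past row length")
        return out

    def reverse_synapses(self, i: int) -> list:
        self._check_post(i)
        out = []
        for j in range(self.M):
            self.counters.reads_pt += 1
            cursor = 0
            for is_run, value in self.row_records[j]:
                self.counters.reads_wt += 1
                if is_run:
                    cursor += value
                else:
                    if cursor == i:
                        out.append(Synapse(j, i, float(self.data[value])))
                    cursor += 1
                if cursor > i:
                    break
        return out

    def _charge_locate(self, j: int, i: int) -> None:
        self.counters.reads_pt += 1
        cursor = 0
        for is_run, value in self.row_records[j]:
            self.counters.reads_wt += 1
            if is_run:
                cursor += value
            else:
                if cursor == i:
                    return
                cursor += 1
            if cursor > i:
                break

    def read_col(self, i: int):
        syns = self.reverse_synapses(i)
        return (np.array([s.pre for s in syns], dtype=np.int64),
                np.array([s.weight for s in syns], dtype=float))

    def add_col(self, i: int, pres: np.ndarray, deltas: np.ndarray) -> None:
        for j, d in zip(pres, deltas):
            self.data[self._locate(j, int(i))] += d
        self.counters.writes_wt += len(pres)

    def storage_bits(self, weight_bits: int) -> CostBreakdown:
        run_field = math.ceil(math.log2(self.N)) if self.N > 1 else 1  # runs in [1, N]
        wt = (self.n_weight_records * (1 + weight_bits)
              + self.n_run_records * (1 + run_field))
        pt = self.M * pointer_bits(self.n_records)
        return CostBreakdown(0, pt, wt)

    def dump_tables(self) -> dict:
        records = []
        starts = []
        for recs in self.row_records:
            starts.append(len(records))
            for is_run, value in recs:
                records.append([1, int(value)] if is_run
                               else [0, float(self.data[value])])
        return {"format": self.format_tag, "PT": starts, "WT": records}


class BitmapStore(_PointerStore):
    """Pointer-based bitmap: dense binary AT plus compact pointer-addressed WT."""

    format_tag = "bmp"

    def __init__(self, dense: DenseConnectivity):
        super().__init__(dense)
        self.at = dense.exists.copy()

    def charge_forward(self, j: int) -> None:
        self._check_pre(j)
        self.counters.reads_pt += 1
        self.counters.reads_at += self.N
        self.counters.reads_wt += int(self.indptr[j + 1] - self.indptr[j])

    def forward_synapses(self, j: int) -> list:
        self.charge_forward(j)
        out = []
        ptr = int(self.indptr[j])
        for i in range(self.N):
            if self.at[j, i]:
                out.append(Synapse(j, i, float(self.data[ptr])))
                ptr += 1
        return out

    def reverse_synapses(self, i: int) -> list:
        """Sweep: probe AT(j, i) for every row; for connected rows walk the
        remaining AT bits to locate the weight offset."""
        self._check_post(i)
        out = []
        for j in range(self.M):
            self.counters.reads_at += 1
            if self.at[j, i]:
                self.counters.reads_at += self.N - 1
                self.counters.reads_pt += 1
                offset = int(self.at[j, :i].sum())
                self.counters.reads_wt += 1
                out.append(Synapse(j, i, float(self.data[self.indptr[j] + offset])))
        return out

    def _charge_locate(self, j: int, i: int) -> None:
        self.counters.reads_pt += 1
        self.counters.reads_at += i + 1
        self.counters.reads_wt += 1

    def read_col(self, i: int):
        pres = np.nonzero(self.at[:, i])[0]
        self.counters.reads_at += self.M + len(pres) * (self.N - 1)
        self.counters.reads_pt += len(pres)
        self.counters.reads_wt += len(pres)
        weights = np.array(
            [self.data[self.indptr[j] + int(self.at[j, :i].sum())] for j in pres],
            dtype=float,
        )
        return pres.astype(np.int64), weights

    def add_col(self, i: int, pres: np.ndarray, deltas: np.ndarray) -> None:
        for j, d in zip(pres, deltas):
            self.data[self._locate(j, int(i))] += d
        self.counters.writes_wt += len(pres)

    def storage_bits(self, weight_bits: int) -> CostBreakdown:
        nnz = self.n_connections
        return CostBreakdown(
            self.M * self.N,
            self.M * pointer_bits(nnz),
            nnz * weight_bits,
        )

    def dump_tables(self) -> dict:
        return {
            "format": self.format_tag,
            "AT": ["".join("1" if b else "0" for b in row) for row in self.at],
            "PT": [int(p) for p in self.indptr[:-1]],
            "WT": [float(w) for w in self.data],
        }


_STORE_CLASSES = {
    "crossbar": CrossbarStore,
    "csr": CSRStore,
    "rle": RLEStore,
    "bmp": BitmapStore,
}


def build_store(dense: DenseConnectivity, format: str) -> SynapticStore:
    """Encode a dense network into one of the four memory arrangements."""
    try:
        cls = _STORE_CLASSES[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    return cls(dense)
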