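"""Fixed-point k-NN classifier mirroring a streaming FPGA accelerator.

The deployed datapath: features are quantized to 8 bits, training vectors
live in a 600-entry ROM, squared Euclidean distances (sum over features of
``mult(|x-y|, |x-y|)``, the squaring routed through a pluggable 8x8
multiplier) are streamed in ROM order into a *sort network & label finder*
(SNLF) -- two banks of 7 cache registers served on alternating cycles
(ping-pong) -- and the 7 globally smallest distances vote the class.

k is fixed at 7 and ROM capacity at 600, matching the deployed design.
Tie-breaking everywhere: smaller distance first, then smaller ROM index;
label ties in the vote break on smaller summed distance, then smaller label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, NamedTuple, Sequence, Tuple

import numpy as np

__all__ = [
    "K_NEIGHBORS",
    "ROM_CAPACITY",
    "MAX_DISTANCE",
    "QuantizationParams",
    "RomEntry",
    "Rom",
    "NeighborRecord",
    "SnlfState",
    "fit_quantizer",
    "quantize",
    "build_rom",
    "squared_distance",
    "snlf_run",
    "snlf_stream",
    "vote",
    "classify",
    "classify_batch",
    "knn_oracle",
    "square_table",
]

K_NEIGHBORS = 7
ROM_CAPACITY = 600
N_CLASSES = 6
#: largest representable squared distance for 4 features of 8 bits (18-bit range)
MAX_DISTANCE = 4 * 255 * 255


class DegenerateFeatureError(ValueError):
    """A feature is constant on the training data and cannot be scaled."""


@dataclass(frozen=True)
class QuantizationParams:
    """Per-feature affine map to [0, 255], fitted on training data only."""

    feature_names: Tuple[str, ...]
    mins: Tuple[float, ...]
    maxs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.feature_names) == len(self.mins) == len(self.maxs)):
            raise ValueError("feature_names, mins and maxs must have equal length")
        for name, lo, hi in zip(self.feature_names, self.mins, self.maxs):
            if not hi > lo:
                raise DegenerateFeatureError(f"feature '{name}' has max <= min ({hi} <= {lo})")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "mins": list(self.mins),
                "maxs": list(self.maxs),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantizationParams":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            mins=tuple(d["mins"]),
            maxs=tuple(d["maxs"]),
        )


def fit_quantizer(X: np.ndarray, feature_names: Sequence[str]) -> QuantizationParams:
    """Fit min-max ranges per feature; raises on constant features."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError("X must be 2-D with one column per feature name")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    for j, name in enumerate(feature_names):
        if not maxs[j] > mins[j]:
            raise DegenerateFeatureError(f"feature '{name}' is constant on the training data")
    return QuantizationParams(tuple(feature_names), tuple(mins.tolist()), tuple(maxs.tolist()))


def quantize(params: QuantizationParams, X: np.ndarray) -> np.ndarray:
    """Affine map ``x -> round(255*(x-min)/(max-min))``, round-half-up, clamped."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mins = np.array(params.mins)
    maxs = np.array(params.maxs)
    scaled = 255.0 * (X - mins) / (maxs - mins)
    q = np.floor(scaled + 0.5)  # round half up
    return np.clip(q, 0, 255).astype(np.uint8)


class RomEntry(NamedTuple):
    features: Tuple[int, ...]
    label: int
    index: int


@dataclass
class Rom:
    """The classifier's training store: quantized vectors + labels, <= 600 entries."""

    entries: List[RomEntry]
    params: QuantizationParams

    def __post_init__(self) -> None:
        if len(self.entries) > ROM_CAPACITY:
            raise ValueError(f"ROM capacity is {ROM_CAPACITY}, got {len(self.entries)} entries")
        for pos, e in enumerate(self.entries):
            if e.index != pos:
                raise ValueError("ROM indices must be 0..len-1 without gaps")
            if not (0 <= e.label < N_CLASSES):
                raise ValueError(f"ROM entry {pos}: label {e.label} out of range")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_features(self) -> int:
        return len(self.params.feature_names)

    def feature_matrix(self) -> np.ndarray:
        return np.array([e.features for e in self.entries], dtype=np.int64)

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=np.int64)

    # -- hex memory-init export (one word per line: feature bytes then label byte),
    #    loadable by Verilog-style $readmemh; quantization params go in a JSON sidecar.
    def to_hex_lines(self) -> List[str]:
        lines = []
        for e in self.entries:
            word = "".join(f"{v:02x}" for v in e.features) + f"{e.label:02x}"
            lines.append(word)
        return lines

    @classmethod
    def from_hex_lines(cls, lines: Sequence[str], params: QuantizationParams) -> "Rom":
        n_feat = len(params.feature_names)
        entries = []
        for pos, line in enumerate(lines):
            line = line.strip()
            if not line:
                continue
            if len(line) != 2 * n_feat + 2:
                raise ValueError(f"ROM line {pos}: expected {2 * n_feat + 2} hex chars, got {len(line)}")
            feats = tuple(int(line[2 * j: 2 * j + 2], 16) for j in range(n_feat))
            label = int(line[2 * n_feat:], 16)
            entries.append(RomEntry(feats, label, len(entries)))
        return cls(entries=entries, params=params)


def build_rom(
    X_train: np.ndarray,
    y_train: np.ndarray,
    params: QuantizationParams,
    rom_size: int = ROM_CAPACITY,
    seed: int = 0,
) -> Rom:
    """Stratified subsample of the training split into the ROM.

    Quota is ``rom_size // n_classes`` per class where available; classes with
    fewer samples contribute everything and the shortfall is redistributed to
    the remaining classes by largest remainder of their proportional share.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if rom_size > ROM_CAPACITY:
        raise ValueError(f"rom_size may not exceed {ROM_CAPACITY}")
    rng = np.random.default_rng(seed)
    counts = {c: int(np.sum(y_train == c)) for c in range(N_CLASSES)}
    base = rom_size // N_CLASSES
    take = {c: min(base, counts[c]) for c in range(N_CLASSES)}
    # redistribute shortfall proportionally to remaining headroom
    leftover = rom_size - sum(take.values())
    while leftover > 0:
        headroom = {c: counts[c] - take[c] for c in range(N_CLASSES) if counts[c] > take[c]}
        if not headroom:
            break
        total_head = sum(headroom.values())
        shares = {c: leftover * h / total_head for c, h in headroom.items()}
        added = 0
        for c in sorted(headroom):
            inc = min(int(shares[c]), headroom[c])
            take[c] += inc
            added += inc
        if added == 0:  # largest remainder, one at a time
            c_best = max(sorted(headroom), key=lambda c: shares[c])
            take[c_best] += 1
            added = 1
        leftover -= added
    entries: List[RomEntry] = []
    Xq = quantize(params, X_train)
    for c in range(N_CLASSES):
        idx = np.flatnonzero(y_train == c)
        if take[c] > 0:
            chosen = rng.choice(idx, size=take[c], replace=False)
            for i in np.sort(chosen):
                entries.append(RomEntry(tuple(int(v) for v in Xq[i]), c, len(entries)))
    return Rom(entries=entries, params=params)


def squared_distance(
    x: Sequence[int], y: Sequence[int], mult: Callable[[int, int], int]
) -> int:
    """Squared Euclidean distance with squaring routed through ``mult``.

    The absolute difference is exact integer arithmetic; accumulation is
    exact (no saturation); evaluation order has no numeric effect.
    """
    if len(x) != len(y):
        raise ValueError("feature vectors must have equal length")
    d = 0
    for xi, yi in zip(x, y):
        diff = abs(int(xi) - int(yi))
        d += mult(diff, diff)
    return d


class NeighborRecord(NamedTuple):
    distance: int
    label: int
    index: int


_SENTINEL = NeighborRecord(MAX_DISTANCE, -1, 1 << 30)


def _beats(a: NeighborRecord, b: NeighborRecord) -> bool:
    """True when ``a`` ranks before ``b``: smaller distance, then smaller index."""
    return (a.distance, a.index) < (b.distance, b.index)


@dataclass
class SnlfState:
    """The sort network & label finder: 14 cache registers in two parity banks.

    Registers initialize to the maximum representable distance; distances
    arriving on odd cycles compete in the Ox bank, even cycles in the Ex bank.
    """

    odd_bank: List[NeighborRecord] = field(default_factory=lambda: [_SENTINEL] * K_NEIGHBORS)
    even_bank: List[NeighborRecord] = field(default_factory=lambda: [_SENTINEL] * K_NEIGHBORS)
    cycle: int = 0

    def insert(self, rec: NeighborRecord) -> None:
        """One streaming step: compare against the bank's current maximum."""
        bank = self.odd_bank if self.cycle % 2 == 0 else self.even_bank
        worst_pos = 0
        for i in range(1, K_NEIGHBORS):
            if _beats(bank[worst_pos], bank[i]):
                worst_pos = i
        if _beats(rec, bank[worst_pos]):
            bank[worst_pos] = rec
        self.cycle += 1

    def merged_top7(self) -> List[NeighborRecord]:
        all_regs = [r for r in self.odd_bank + self.even_bank if r.label >= 0]
        all_regs.sort(key=lambda r: (r.distance, r.index))
        return all_regs[:K_NEIGHBORS]


def snlf_run(rom: Rom, x: Sequence[int], mult: Callable[[int, int], int]) -> SnlfState:
    """Stream every ROM entry through the selection network; returns the state."""
    if len(rom) == 0:
        raise ValueError("ROM is empty")
    state = SnlfState()
    for e in rom.entries:
        d = squared_distance(x, e.features, mult)
        state.insert(NeighborRecord(d, e.label, e.index))
    return state


def snlf_stream(
    rom: Rom, x: Sequence[int], mult: Callable[[int, int], int]
) -> List[NeighborRecord]:
    """The 7 globally smallest distance records after the full ROM stream."""
    return snlf_run(rom, x, mult).merged_top7()


def vote(neighbors: Sequence[NeighborRecord]) -> int:
    """Plurality label of 7 neighbors; ties break on smaller summed distance
    among tied labels, then smaller label id."""
    if len(neighbors) != K_NEIGHBORS:
        raise ValueError(f"vote requires exactly {K_NEIGHBORS} neighbors")
    count: Dict[int, int] = {}
    dist_sum: Dict[int, int] = {}
    for r in neighbors:
        count[r.label] = count.get(r.label, 0) + 1
        dist_sum[r.label] = dist_sum.get(r.label, 0) + r.distance
    return min(count, key=lambda lab: (-count[lab], dist_sum[lab], lab))


def classify(x: Sequence[float], rom: Rom, mult: Callable[[int, int], int]) -> int:
    """Quantize -> stream through the SNLF -> vote. The faithful datapath."""
    xq = quantize(rom.params, np.asarray(x, dtype=float))[0]
    return vote(snlf_stream(rom, xq, mult))


def knn_oracle(x: Sequence[float], rom: Rom, k: int = K_NEIGHBORS) -> int:
    """Reference classifier: full sort of all exact distances, same tie rule."""
    xq = quantize(rom.params, np.asarray(x, dtype=float))[0].astype(np.int64)
    feats = rom.feature_matrix()
    dists = ((feats - xq) ** 2).sum(axis=1)
    order = np.argsort(dists, kind="stable")[:k]  # stable sort = index tie-break
    recs = [NeighborRecord(int(dists[i]), int(rom.entries[i].label), int(i)) for i in order]
    if k == K_NEIGHBORS:
        return vote(recs)
    count: Dict[int, int] = {}
    dist_sum: Dict[int, int] = {}
    for r in recs:
        count[r.label] = count.get(r.label, 0) + 1
        dist_sum[r.label] = dist_sum.get(r.label, 0) + r.distance
    return min(count, key=lambda lab: (-count[lab], dist_sum[lab], lab))


def square_table(mult: Callable[[int, int], int] | None = None) -> np.ndarray:
    """256-entry table of ``mult(v, v)``; exact squares when ``mult`` is None.

    Distance evaluation only ever multiplies a difference by itself, so the
    multiplier's diagonal fully determines classification behaviour.
    """
    if mult is None:
        v = np.arange(256, dtype=np.int64)
        return v * v
    return np.array([mult(v, v) for v in range(256)], dtype=np.int64)


def classify_batch(X: np.ndarray, rom: Rom, sq_table: np.ndarray | None = None) -> np.ndarray:
    """Vectorized classification of many real-valued queries.

    Uses the same (distance, ROM index) order as the streaming network --
    the two routes provably select the same 7 neighbors; tests assert it.
    """
    if sq_table is None:
        sq_table = square_table(None)
    Xq = quantize(rom.params, np.asarray(X, dtype=float)).astype(np.int64)
    feats = rom.feature_matrix()
    labels = rom.labels()
    diffs = np.abs(Xq[:, None, :] - feats[None, :, :])
    dists = sq_table[diffs].sum(axis=2)
    out = np.empty(len(Xq), dtype=np.int64)
    for qi in range(len(Xq)):
        order = np.argsort(dists[qi], kind="stable")[:K_NEIGHBORS]
        recs = [NeighborRecord(int(dists[qi, i]), int(labels[i]), int(i)) for i in order]
        out[qi] = vote(recs)
    return out
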