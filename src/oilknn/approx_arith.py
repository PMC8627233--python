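"""Bit-accurate emulation of a LUT-based approximate integer multiplier.

The target device builds arithmetic out of k-input look-up tables (k = 4, 5,
6).  A 4x4 multiplier is decomposed as ``n*m = n*(m1 m0) + (n*(m3 m2) << 2)``:
each bit of the two 6-bit partial results is enumerated into its own LUT, the
low product bits come out of those LUTs directly, and the upper bits are
recombined with a 4-bit carry-lookahead adder whose generate/propagate signals
are themselves LUT outputs.  Four such 4x4 units compose an 8x8 multiplier
whose middle segment is summed *without* carry into the top nibble -- the
deliberate approximation that saves hardware.

Two ready-made 4x4 configurations are provided:

``functional_mult4_config()``
    Every LUT's init vector is derived here from its functional role
    (partial-product bit, exact generate/propagate, carry-free sum).  The
    resulting 4x4 unit is an exact multiplier.

``table10_mult4_config()``
    The init vectors as printed in the source hardware description (with two
    obvious transcription fixes, see the docstring).  Its ``g0``/``r0`` LUTs
    approximate the carry out of product bit 2, so this unit is itself
    approximate; ``error_profile`` quantifies by how much.

Address convention: a LUT's inputs are listed most-significant first
(I5 ... I0); I0 is the least-significant address bit, and bit ``j`` of the
init value (LSB = bit 0) is the output for address ``j``.  A label of ``"1"``
denotes an input tied high.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "LutConfig",
    "Mult4Config",
    "ErrorProfile",
    "lut_eval",
    "mult4_exact_decomposed",
    "mult4_table",
    "cla4",
    "mult8_approx",
    "error_profile",
    "multiplier_table",
    "mult8_table_from_sub",
    "functional_mult4_config",
    "table10_mult4_config",
    "config_to_json",
    "config_from_json",
    "compare_configs",
]

_VALID_WIDTHS = (4, 5, 6)


@dataclass(frozen=True)
class LutConfig:
    """One k-input look-up table: the atomic arithmetic primitive."""

    name: str
    width: int
    init: int
    input_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.width not in _VALID_WIDTHS:
            raise ValueError(f"LUT {self.name}: width must be one of {_VALID_WIDTHS}, got {self.width}")
        n_entries = 1 << self.width
        if not (0 <= self.init < (1 << n_entries)):
            raise ValueError(f"LUT {self.name}: init value does not fit {n_entries} truth-table bits")
        if len(self.input_labels) != self.width:
            raise ValueError(
                f"LUT {self.name}: {len(self.input_labels)} input labels for width {self.width}"
            )

    @property
    def init_hex(self) -> str:
        """Init vector as a fixed-width hex string (2^width bits)."""
        return format(self.init, f"0{(1 << self.width) // 4}x")

    @classmethod
    def from_hex(cls, name: str, init_hex: str, input_labels: Sequence[str]) -> "LutConfig":
        width = len(input_labels)
        expected_chars = (1 << width) // 4
        if len(init_hex) != expected_chars:
            raise ValueError(
                f"LUT {name}: init hex '{init_hex}' has {len(init_hex)} chars, expected {expected_chars}"
            )
        return cls(name=name, width=width, init=int(init_hex, 16), input_labels=tuple(input_labels))

    @classmethod
    def from_function(
        cls, name: str, input_labels: Sequence[str], fn: Callable[[Mapping[str, int]], int]
    ) -> "LutConfig":
        """Enumerate ``fn`` over all input assignments to build the init vector.

        ``fn`` receives a mapping from input label to bit value; the label
        ``"1"`` marks a tied-high input.  Addresses where a tied-high bit is
        0 are unreachable in hardware and are filled with 0, matching the
        convention used for printed init vectors.
        """
        labels = tuple(input_labels)
        width = len(labels)
        init = 0
        for addr in range(1 << width):
            env = {}
            reachable = True
            for j in range(width):
                lab = labels[width - 1 - j]  # labels listed I_{w-1} ... I_0
                bit = (addr >> j) & 1
                if lab == "1" and bit == 0:
                    reachable = False
                    break
                env[lab] = bit
            if reachable and fn(env) & 1:
                init |= 1 << addr
        return cls(name=name, width=width, init=init, input_labels=labels)


def lut_eval(cfg: LutConfig, inputs: Sequence[int]) -> int:
    """Evaluate a LUT: ``inputs`` ordered as ``cfg.input_labels`` (I_{w-1} first)."""
    if len(inputs) != cfg.width:
        raise ValueError(f"LUT {cfg.name}: got {len(inputs)} inputs, expected {cfg.width}")
    addr = 0
    for j, bit in enumerate(inputs):
        if bit not in (0, 1):
            raise ValueError(f"LUT {cfg.name}: inputs must be bits, got {bit!r}")
        addr |= bit << (cfg.width - 1 - j)
    return (cfg.init >> addr) & 1


# Output signals a complete 4x4 configuration must provide.
_MULT4_SIGNALS = (
    "p00", "p01", "p02", "p03", "p04", "p05",
    "p11", "p12", "p13", "p14", "p15",
    "g0", "r0", "g1", "r1", "g2", "r2",
    "pp2",
)


@dataclass(frozen=True)
class Mult4Config:
    """A 4x4 multiplier: one LUT per output signal plus implicit wiring.

    The wiring is carried by each LUT's ``input_labels``: labels name either
    multiplier input bits (``n0..n3``, ``m0..m3``), the constant ``"1"``, or
    a previously produced partial-product signal (``p02`` etc.).
    """

    luts: Dict[str, LutConfig] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [s for s in _MULT4_SIGNALS if s not in self.luts]
        if missing:
            raise ValueError(f"Mult4Config '{self.name}' missing LUTs for signals: {missing}")
        produced = set()
        primary = {"1"} | {f"n{i}" for i in range(4)} | {f"m{i}" for i in range(4)}
        # signals evaluated in declaration order of _MULT4_SIGNALS; check no loops
        for sig in _MULT4_SIGNALS:
            for lab in self.luts[sig].input_labels:
                if lab not in primary and lab not in produced:
                    raise ValueError(
                        f"Mult4Config '{self.name}': LUT for {sig} consumes undefined signal '{lab}'"
                    )
            produced.add(sig)


def mult4_exact_decomposed(n: int, m: int) -> int:
    """Structural reference: ``n*(m1 m0) + (n*(m3 m2) << 2)`` with full carry.

    Equals ``n*m`` for all 256 operand pairs; serves as the oracle the LUT
    route is audited against.
    """
    _check_range(n, 15, "n")
    _check_range(m, 15, "m")
    p0 = n * (m & 0x3)
    p1 = n * (m >> 2)
    return p0 + (p1 << 2)


def cla4(
    gen: Tuple[int, int, int],
    prop: Tuple[int, int, int],
    high: Tuple[int, int],
) -> Tuple[int, int, int, int, int]:
    """4-bit carry-lookahead recombination for product bits 3..7.

    ``gen``/``prop`` are the (g0,g1,g2)/(r0,r1,r2) LUT outputs anchored at
    product position 3 (g0/r0 already fold in the carry out of bit 2);
    ``high`` is (p14, p15).  Carries follow ``c[i+1] = g[i] | (r[i] & c[i])``
    with zero carry into the anchor; sums are propagate XOR incoming carry.
    No carry is produced beyond bit 7.
    """
    c = 0
    pp3 = prop[0] ^ c
    c = gen[0] | (prop[0] & c)
    pp4 = prop[1] ^ c
    c = gen[1] | (prop[1] & c)
    pp5 = prop[2] ^ c
    c = gen[2] | (prop[2] & c)
    pp6 = high[0] ^ c
    c = high[0] & c
    pp7 = high[1] ^ c
    return (pp3, pp4, pp5, pp6, pp7)


def mult4_table(n: int, m: int, cfg: Mult4Config) -> int:
    """Evaluate the configured LUT network for one 4x4 product."""
    _check_range(n, 15, "n")
    _check_range(m, 15, "m")
    env: Dict[str, int] = {"1": 1}
    for i in range(4):
        env[f"n{i}"] = (n >> i) & 1
        env[f"m{i}"] = (m >> i) & 1

    def ev(sig: str) -> int:
        cfg_l = cfg.luts[sig]
        return lut_eval(cfg_l, [env[lab] for lab in cfg_l.input_labels])

    for sig in ("p00", "p01", "p02", "p03", "p04", "p05", "p11", "p12", "p13", "p14", "p15"):
        env[sig] = ev(sig)
    pp2 = ev("pp2")
    gen = (ev("g0"), ev("g1"), ev("g2"))
    prop = (ev("r0"), ev("r1"), ev("r2"))
    pp3, pp4, pp5, pp6, pp7 = cla4(gen, prop, (env["p14"], env["p15"]))
    bits_out = (env["p00"], env["p01"], pp2, pp3, pp4, pp5, pp6, pp7)
    return sum(b << k for k, b in enumerate(bits_out))


def mult8_approx(a: int, b: int, sub: Callable[[int, int], int]) -> int:
    """8x8 multiplier composed of four 4x4 blocks with a carry-free middle sum.

    With nibbles aL/aH and bL/bH: P0 = sub(aL,bL), P1 = sub(aH,bL),
    P2 = sub(aL,bH), P3 = sub(aH,bH).  Result bits 0-3 come from P0 and bits
    12-15 from P3 directly; bits 4-11 are the middle contributions summed
    with carries out of bit 11 discarded and no carry into the top nibble.
    """
    _check_range(a, 255, "a")
    _check_range(b, 255, "b")
    a_lo, a_hi = a & 0xF, a >> 4
    b_lo, b_hi = b & 0xF, b >> 4
    p0 = sub(a_lo, b_lo)
    p1 = sub(a_hi, b_lo)
    p2 = sub(a_lo, b_hi)
    p3 = sub(a_hi, b_hi)
    mid = (p0 >> 4) + p1 + p2 + ((p3 & 0xF) << 4)
    return (p0 & 0xF) | ((mid & 0xFF) << 4) | ((p3 >> 4) << 12)


# ---------------------------------------------------------------------------
# ready-made configurations


def functional_mult4_config() -> Mult4Config:
    """Exact 4x4 configuration, each init derived from the LUT's role.

    Partial-product LUTs hold bit ``i`` of ``n*(m1 m0)`` (resp. ``n*(m3 m2)``);
    g0/r0 hold the exact carry-out/sum-bit of product position 3 including
    the carry ``p02 & m2 & n0`` out of bit 2; g1/r1 and g2/r2 are plain
    AND/XOR generate/propagate pairs; pp2 is the carry-free half-adder sum.
    """

    def p_bit(i: int, hi_pair: bool) -> Callable[[Mapping[str, int]], int]:
        def fn(e: Mapping[str, int]) -> int:
            n = e.get("n0", 0) | e.get("n1", 0) << 1 | e.get("n2", 0) << 2 | e.get("n3", 0) << 3
            if hi_pair:
                m = e.get("m2", 0) | e.get("m3", 0) << 1
            else:
                m = e.get("m0", 0) | e.get("m1", 0) << 1
            return (n * m >> i) & 1
        return fn

    def carry_bit2(e: Mapping[str, int]) -> int:
        return e["p02"] & e["m2"] & e["n0"]

    luts = {
        "p00": LutConfig.from_function("Lut4_0", ("1", "1", "m0", "n0"), p_bit(0, False)),
        "p01": LutConfig.from_function("Lut4_1", ("m1", "m0", "n1", "n0"), p_bit(1, False)),
        "p02": LutConfig.from_function("Lut5_0", ("m1", "m0", "n2", "n1", "n0"), p_bit(2, False)),
        "p03": LutConfig.from_function("Lut6_0", ("m1", "m0", "n3", "n2", "n1", "n0"), p_bit(3, False)),
        "p04": LutConfig.from_function("Lut6_1", ("m1", "m0", "n3", "n2", "n1", "n0"), p_bit(4, False)),
        "p05": LutConfig.from_function("Lut6_2", ("m1", "m0", "n3", "n2", "n1", "n0"), p_bit(5, False)),
        "p11": LutConfig.from_function("Lut4_2", ("m3", "m2", "n1", "n0"), p_bit(1, True)),
        "p12": LutConfig.from_function("Lut5_1", ("m3", "m2", "n2", "n1", "n0"), p_bit(2, True)),
        "p13": LutConfig.from_function("Lut6_3", ("m3", "m2", "n3", "n2", "n1", "n0"), p_bit(3, True)),
        "p14": LutConfig.from_function("Lut6_4", ("m3", "m2", "n3", "n2", "n1", "n0"), p_bit(4, True)),
        "p15": LutConfig.from_function("Lut6_5", ("m3", "m2", "n3", "n2", "n1", "n0"), p_bit(5, True)),
        "g0": LutConfig.from_function(
            "Lut5_2", ("p11", "p03", "m2", "n0", "p02"),
            lambda e: 1 if (e["p03"] + e["p11"] + carry_bit2(e)) >= 2 else 0,
        ),
        "r0": LutConfig.from_function(
            "Lut5_3", ("p11", "p03", "m2", "n0", "p02"),
            lambda e: e["p03"] ^ e["p11"] ^ carry_bit2(e),
        ),
        "g1": LutConfig.from_function("Lut4_3", ("1", "1", "p12", "p04"), lambda e: e["p12"] & e["p04"]),
        "r1": LutConfig.from_function("Lut4_4", ("1", "1", "p12", "p04"), lambda e: e["p12"] ^ e["p04"]),
        "g2": LutConfig.from_function("Lut4_5", ("1", "1", "p13", "p05"), lambda e: e["p13"] & e["p05"]),
        "r2": LutConfig.from_function("Lut4_6", ("1", "1", "p13", "p05"), lambda e: e["p13"] ^ e["p05"]),
        "pp2": LutConfig.from_function("Lut4_7", ("1", "p02", "m2", "n0"), lambda e: e["p02"] ^ (e["m2"] & e["n0"])),
    }
    return Mult4Config(luts=luts, name="functional")


# Init vectors as printed in the hardware description.  Two transcription
# fixes relative to the printed text: the init "6aco" is read as hex 6ac0
# ('o' for '0'), and the inputs of the three LUTs feeding p03/p04/p05 are
# m1,m0 (bits of the low m pair those product bits depend on) where the
# printed subscripts slipped by one.  Everything else is verbatim; use
# compare_configs()/the audit CLI to see where it deviates from the exact
# functional derivation (the g0/r0 carry approximation).
_TABLE10 = {
    "p00": ("Lut4_0", "8000", ("1", "1", "m0", "n0")),
    "p01": ("Lut4_1", "6ac0", ("m1", "m0", "n1", "n0")),
    "p02": ("Lut5_0", "b4ccf000", ("m1", "m0", "n2", "n1", "n0")),
    "p03": ("Lut6_0", "c738f0f0ff000000", ("m1", "m0", "n3", "n2", "n1", "n0")),
    "p04": ("Lut6_1", "07c0ff0000000000", ("m1", "m0", "n3", "n2", "n1", "n0")),
    "p05": ("Lut6_2", "f800000000000000", ("m1", "m0", "n3", "n2", "n1", "n0")),
    "p11": ("Lut4_2", "6ac0", ("m3", "m2", "n1", "n0")),
    "p12": ("Lut5_1", "b4ccf000", ("m3", "m2", "n2", "n1", "n0")),
    "p13": ("Lut6_3", "c738f0f0ff000000", ("m3", "m2", "n3", "n2", "n1", "n0")),
    "p14": ("Lut6_4", "07c0ff0000000000", ("m3", "m2", "n3", "n2", "n1", "n0")),
    "p15": ("Lut6_5", "f800000000000000", ("m3", "m2", "n3", "n2", "n1", "n0")),
    "g0": ("Lut5_2", "ffeaea00", ("p11", "p03", "m2", "n0", "p02")),
    "r0": ("Lut5_3", "007f7f80", ("p11", "p03", "m2", "n0", "p02")),
    "g1": ("Lut4_3", "8000", ("1", "1", "p12", "p04")),
    "r1": ("Lut4_4", "6000", ("1", "1", "p12", "p04")),
    "g2": ("Lut4_5", "8000", ("1", "1", "p13", "p05")),
    "r2": ("Lut4_6", "6000", ("1", "1", "p13", "p05")),
    "pp2": ("Lut4_7", "7800", ("1", "p02", "m2", "n0")),
}


def table10_mult4_config() -> Mult4Config:
    """The printed 4x4 configuration (approximate g0/r0 carry handling)."""
    luts = {
        sig: LutConfig.from_hex(name, hexval, labels)
        for sig, (name, hexval, labels) in _TABLE10.items()
    }
    return Mult4Config(luts=luts, name="table10")


def compare_configs(a: Mult4Config, b: Mult4Config) -> Dict[str, Tuple[str, str]]:
    """Map of signal -> (a init hex, b init hex) for every differing LUT."""
    out = {}
    for sig in _MULT4_SIGNALS:
        if a.luts[sig].init != b.luts[sig].init:
            out[sig] = (a.luts[sig].init_hex, b.luts[sig].init_hex)
    return out


# ---------------------------------------------------------------------------
# serialization

def config_to_json(cfg: Mult4Config) -> str:
    obj = {
        "name": cfg.name,
        "luts": {
            sig: {
                "name": lut.name,
                "width": lut.width,
                "init": lut.init_hex,
                "input_labels": list(lut.input_labels),
            }
            for sig, lut in sorted(cfg.luts.items())
        },
    }
    return json.dumps(obj, indent=2, sort_keys=True)


def config_from_json(text: str) -> Mult4Config:
    obj = json.loads(text)
    luts = {}
    for sig, d in obj["luts"].items():
        lut = LutConfig.from_hex(d["name"], d["init"], d["input_labels"])
        if lut.width != d["width"]:
            raise ValueError(f"LUT {d['name']}: declared width {d['width']} != {lut.width}")
        luts[sig] = lut
    return Mult4Config(luts=luts, name=obj.get("name", "custom"))


# ---------------------------------------------------------------------------
# exhaustive error characterization

@dataclass
class ErrorProfile:
    """Exhaustive comparison of a multiplier against exact products."""

    operand_width: int
    total_pairs: int
    error_count: int
    error_rate: float
    mean_error_distance: float
    mean_relative_error_distance: float
    max_absolute_error: int
    error_histogram: Dict[int, float]

    def to_dict(self) -> dict:
        return {
            "operand_width": self.operand_width,
            "total_pairs": self.total_pairs,
            "error_count": self.error_count,
            "error_rate": self.error_rate,
            "mean_error_distance": self.mean_error_distance,
            "mean_relative_error_distance": self.mean_relative_error_distance,
            "max_absolute_error": self.max_absolute_error,
            "error_histogram": {str(k): v for k, v in sorted(self.error_histogram.items())},
        }


def multiplier_table(mult_fn: Callable[[int, int], int], width: int) -> np.ndarray:
    """Tabulate ``mult_fn`` over its full operand grid (2^width squared)."""
    n = 1 << width
    table = np.empty((n, n), dtype=np.int64)
    for a in range(n):
        for b in range(n):
            table[a, b] = mult_fn(a, b)
    return table


def mult8_table_from_sub(sub_table: np.ndarray) -> np.ndarray:
    """Vectorized 256x256 table of the 8x8 composition over a 16x16 sub table."""
    if sub_table.shape != (16, 16):
        raise ValueError("sub_table must be 16x16")
    a = np.arange(256)[:, None]
    b = np.arange(256)[None, :]
    a_lo, a_hi = a & 0xF, a >> 4
    b_lo, b_hi = b & 0xF, b >> 4
    p0 = sub_table[a_lo, b_lo]
    p1 = sub_table[a_hi, b_lo]
    p2 = sub_table[a_lo, b_hi]
    p3 = sub_table[a_hi, b_hi]
    mid = (p0 >> 4) + p1 + p2 + ((p3 & 0xF) << 4)
    return (p0 & 0xF) | ((mid & 0xFF) << 4) | ((p3 >> 4) << 12)


def error_profile(
    mult_fn: Callable[[int, int], int] | None,
    width: int,
    *,
    table: np.ndarray | None = None,
) -> ErrorProfile:
    """Exhaustive sweep of all operand pairs against exact products.

    Either a scalar ``mult_fn`` or a precomputed product ``table`` may be
    supplied; the table route avoids per-pair Python calls at width 8.
    """
    if width not in (4, 8):
        raise ValueError("width must be 4 or 8")
    if table is None:
        if mult_fn is None:
            raise ValueError("either mult_fn or table is required")
        table = multiplier_table(mult_fn, width)
    n = 1 << width
    exact = np.arange(n)[:, None] * np.arange(n)[None, :]
    err = table.astype(np.int64) - exact
    abs_err = np.abs(err)
    total = n * n
    error_count = int(np.count_nonzero(err))
    rel = abs_err / np.maximum(exact, 1)
    values, counts = np.unique(err, return_counts=True)
    hist = {int(v): float(c) / total for v, c in zip(values, counts)}
    return ErrorProfile(
        operand_width=width,
        total_pairs=total,
        error_count=error_count,
        error_rate=error_count / total,
        mean_error_distance=float(abs_err.mean()),
        mean_relative_error_distance=float(rel.mean()),
        max_absolute_error=int(abs_err.max()),
        error_histogram=hist,
    )


def _check_range(v: int, hi: int, name: str) -> None:
    if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
        raise TypeError(f"{name} must be an integer, got {type(v).__name__}")
    if not (0 <= v <= hi):
        raise ValueError(f"{name} out of range [0, {hi}]: {v}")
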