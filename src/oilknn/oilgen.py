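"""Synthetic oil-sample generator: the 3,600-sample, 4-group mixing design.

Fifteen base oils in six classes (2 gutter, 4 chili/capsicol, 2 soybean,
2 colza, 3 peanut, 2 olive) are measured on nine physicochemical features:
pH at 25/60 degC, conductivity at 25/60 degC plus its difference, peroxide
value at 25/60 degC plus its difference, and refractive index at 25 degC.

The four groups:

* Group 1 -- the 15 pure oils.
* Group 2 -- each pure oil with one of the 15 four-of-six seasoning
  combinations (C(6,4) = 15): 225 samples.
* Group 3 -- every ordered pair of distinct pure oils mixed 80:20:
  15*14 = 210 samples.
* Group 4 -- each Group-3 mixture with each seasoning combination:
  210*15 = 3,150 samples.  Total 3,600.

Labels: a sample containing *any* gutter-oil component is labeled gutter oil;
otherwise it takes the class of its 80% majority component.

pH anchors are measured values; conductivity, peroxide and refractive-index
anchors are synthetic values chosen to respect the documented qualitative
orderings (gutter conductivity at 60 degC and peroxide at 25 degC are the
highest, gutter peroxide *change* on heating is the lowest, refractive index
of gutter oil sits below 1.4730 within the 1.4713-1.4768 band).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "PRIMITIVE_FEATURES",
    "CLASSES",
    "SEASONINGS",
    "BaseOilProfile",
    "SeasoningCombo",
    "GeneratorConfig",
    "base_profiles",
    "seasoning_combos",
    "mix_features",
    "label_rule",
    "generate",
    "split",
    "GROUP_SIZES",
]

#: canonical feature schema (CSV column order)
FEATURES = ("25ph", "60ph", "25conduc", "60conduc", "dvconduc", "25ox", "60ox", "dvox", "reindex")
#: the seven independently measured features; the two dv features are derived
PRIMITIVE_FEATURES = ("25ph", "60ph", "25conduc", "60conduc", "25ox", "60ox", "reindex")
CLASSES = ("gutter", "capsicol", "soybean", "colza", "peanut", "olive")
SEASONINGS = ("sugar_5g", "salt_3g", "msg_2g", "chicken_essence_2g", "soy_sauce_5g", "vinegar_10g")

GROUP_SIZES = {1: 15, 2: 225, 3: 210, 4: 3150}

# anchors: (ph25, ph60, cond25, cond60, ox25, ox60, reindex)
# pH columns are the measured 25/60 degC values; conductivity (uS/cm),
# peroxide (meq/kg) and refractive index are synthetic (see module docstring).
_ANCHORS: Dict[str, Tuple[int, Tuple[float, ...]]] = {
    "gutter_1":   (0, (3.93, 3.38, 16.0, 48.0, 16.0, 18.5, 1.4718)),
    "gutter_2":   (0, (8.85, 9.21, 14.0, 44.0, 15.0, 17.0, 1.4725)),
    "capsicol_1": (1, (5.77, 5.80, 6.0, 20.0, 8.0, 20.0, 1.4762)),
    "capsicol_2": (1, (6.12, 6.16, 6.5, 21.0, 8.5, 21.0, 1.4765)),
    "capsicol_3": (1, (5.98, 5.97, 5.5, 19.0, 7.5, 19.5, 1.4760)),
    "capsicol_4": (1, (6.17, 6.24, 6.2, 20.5, 8.2, 20.2, 1.4768)),
    "soybean_1":  (2, (5.94, 5.90, 3.0, 10.0, 4.0, 16.0, 1.4746)),
    "soybean_2":  (2, (5.10, 5.12, 3.2, 10.5, 4.3, 15.5, 1.4742)),
    "colza_1":    (3, (6.99, 7.00, 4.5, 14.0, 5.5, 13.0, 1.4756)),
    "colza_2":    (3, (7.02, 7.14, 4.3, 13.5, 5.8, 13.4, 1.4753)),
    "peanut_1":   (4, (4.98, 4.88, 2.5, 8.0, 3.0, 11.0, 1.4739)),
    "peanut_2":   (4, (4.55, 4.50, 2.6, 8.3, 3.2, 11.4, 1.4736)),
    "peanut_3":   (4, (4.70, 4.67, 2.4, 7.8, 2.9, 10.8, 1.4741)),
    "olive_1":    (5, (5.71, 5.73, 2.0, 6.0, 2.0, 8.5, 1.4731)),
    "olive_2":    (5, (5.51, 5.55, 1.9, 5.8, 2.1, 8.8, 1.4733)),
}

#: per-feature Gaussian measurement-noise scale (primitive feature order)
_DEFAULT_NOISE = (0.05, 0.05, 0.15, 0.35, 0.15, 0.25, 0.0004)

# additive per-seasoning offsets on the primitive features; mostly ionic
# content raising conductivity, acids lowering pH.  Magnitudes stay within a
# few percent of each feature's range so class structure survives seasoning.
_DEFAULT_SEASONING_EFFECTS: Dict[str, Tuple[float, ...]] = {
    "sugar_5g":           (-0.02, -0.02, 0.05, 0.08, 0.02, 0.03, 0.0002),
    "salt_3g":            (0.0, 0.0, 0.60, 1.00, 0.0, 0.0, 0.0),
    "msg_2g":             (0.0, 0.0, 0.30, 0.50, 0.0, 0.0, 0.0),
    "chicken_essence_2g": (0.0, 0.0, 0.20, 0.35, 0.05, 0.08, 0.0),
    "soy_sauce_5g":       (-0.08, -0.08, 0.50, 0.90, 0.05, 0.05, 0.0001),
    "vinegar_10g":        (-0.30, -0.30, 0.35, 0.55, 0.10, 0.10, 0.0),
}

# physical truncation ranges for the primitive features
_CLIP_LO = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.40])
_CLIP_HI = np.array([14.0, 14.0, np.inf, np.inf, np.inf, np.inf, 1.50])


@dataclass(frozen=True)
class BaseOilProfile:
    """One pure oil: mean feature vector plus per-feature noise scale."""

    id: str
    label: int
    means: Tuple[float, ...]  # primitive feature order
    noise: Tuple[float, ...]

    @property
    def class_name(self) -> str:
        return CLASSES[self.label]

    def full_means(self) -> np.ndarray:
        """Nine-feature mean vector with the dv features derived."""
        return _expand(np.array(self.means))


@dataclass(frozen=True)
class SeasoningCombo:
    """A 4-element subset of the 6 seasonings with its additive effect vector."""

    members: Tuple[int, ...]  # seasoning indices, ascending
    effect: Tuple[float, ...]  # summed additive offsets, primitive feature order

    @property
    def mask(self) -> str:
        """6-character bit string, position i = SEASONINGS[i] present."""
        return "".join("1" if i in self.members else "0" for i in range(len(SEASONINGS)))


@dataclass
class GeneratorConfig:
    """Fully determines the output dataset: same config => identical samples."""

    seed: int = 0
    noise_scales: Tuple[float, ...] = _DEFAULT_NOISE
    seasoning_effects: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SEASONING_EFFECTS)
    )
    #: multiplier on measurement noise for mixed (Group 3/4) samples
    mix_noise_factor: float = 1.0
    #: optional anchor overrides {profile id: 7-tuple of primitive means}
    anchor_overrides: Dict[str, Tuple[float, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise_scales": list(self.noise_scales),
            "seasoning_effects": {k: list(v) for k, v in sorted(self.seasoning_effects.items())},
            "mix_noise_factor": self.mix_noise_factor,
            "anchor_overrides": {k: list(v) for k, v in sorted(self.anchor_overrides.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            seed=d.get("seed", 0),
            noise_scales=tuple(d.get("noise_scales", _DEFAULT_NOISE)),
            seasoning_effects={
                k: tuple(v)
                for k, v in d.get(
                    "seasoning_effects", {k: list(v) for k, v in _DEFAULT_SEASONING_EFFECTS.items()}
                ).items()
            },
            mix_noise_factor=d.get("mix_noise_factor", 1.0),
            anchor_overrides={k: tuple(v) for k, v in d.get("anchor_overrides", {}).items()},
        )


def _expand(primitive: np.ndarray) -> np.ndarray:
    """Primitive 7-vector -> full 9-vector with dv features recomputed."""
    ph25, ph60, c25, c60, ox25, ox60, ri = primitive
    return np.array([ph25, ph60, c25, c60, c60 - c25, ox25, ox60, ox60 - ox25, ri])


def base_profiles(config: Optional[GeneratorConfig] = None) -> List[BaseOilProfile]:
    """The 15-oil roster (2 gutter, 4 capsicol, 2 soybean, 2 colza, 3 peanut, 2 olive)."""
    cfg = config or GeneratorConfig()
    profiles = []
    for pid, (label, means) in _ANCHORS.items():
        m = cfg.anchor_overrides.get(pid, means)
        profiles.append(BaseOilProfile(id=pid, label=label, means=tuple(m), noise=cfg.noise_scales))
    return profiles


def seasoning_combos(config: Optional[GeneratorConfig] = None) -> List[SeasoningCombo]:
    """All C(6,4) = 15 four-element seasoning subsets, lexicographic order."""
    cfg = config or GeneratorConfig()
    combos = []
    for members in itertools.combinations(range(len(SEASONINGS)), 4):
        effect = np.zeros(len(PRIMITIVE_FEATURES))
        for i in members:
            effect += np.array(cfg.seasoning_effects[SEASONINGS[i]])
        combos.append(SeasoningCombo(members=members, effect=tuple(effect.tolist())))
    return combos


def mix_features(
    major: BaseOilProfile,
    minor: BaseOilProfile,
    ratio: float = 0.8,
    rng: Optional[np.random.Generator] = None,
    noise_factor: float = 1.0,
) -> np.ndarray:
    """Convex combination of the primitive features plus seeded noise.

    Returns the full 9-feature vector; the dv features are recomputed after
    mixing and truncation so the definitional identities hold exactly.
    """
    if major.id == minor.id:
        raise ValueError("self-mixing is excluded (major and minor must differ)")
    base = ratio * np.array(major.means) + (1.0 - ratio) * np.array(minor.means)
    if rng is not None:
        base = base + rng.normal(0.0, np.array(major.noise)) * noise_factor
    base = np.clip(base, _CLIP_LO, _CLIP_HI)
    return _expand(base)


def label_rule(component_labels: Sequence[int]) -> int:
    """Gutter label if any component is gutter; else the majority component's class.

    ``component_labels`` is (major,) for pure oils or (major, minor) for mixes.
    """
    if 0 in component_labels:
        return 0
    return component_labels[0]


def _emit(
    rows: list,
    sample_id: int,
    group: int,
    major: BaseOilProfile,
    minor: Optional[BaseOilProfile],
    mask: str,
    features: np.ndarray,
) -> None:
    labels = (major.label,) if minor is None else (major.label, minor.label)
    rows.append(
        {
            "sample_id": sample_id,
            "group": group,
            "major_id": major.id,
            "minor_id": minor.id if minor is not None else "",
            "ratio": 1.0 if minor is None else 0.8,
            "seasoning_mask": mask,
            **{name: features[j] for j, name in enumerate(FEATURES)},
            "label": label_rule(labels),
        }
    )


def generate(config: Optional[GeneratorConfig] = None) -> pd.DataFrame:
    """Generate the full 3,600-sample dataset, fully seed-reproducible."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    profiles = base_profiles(cfg)
    combos = seasoning_combos(cfg)
    rows: list = []
    sid = 0

    def measure(primitive_means: np.ndarray, noise: np.ndarray, factor: float = 1.0) -> np.ndarray:
        sample = primitive_means + rng.normal(0.0, noise) * factor
        sample = np.clip(sample, _CLIP_LO, _CLIP_HI)
        return _expand(sample)

    no_seasoning = "0" * len(SEASONINGS)
    # Group 1: pure oils
    for p in profiles:
        feats = measure(np.array(p.means), np.array(p.noise))
        _emit(rows, sid, 1, p, None, no_seasoning, feats)
        sid += 1
    # Group 2: pure oils with seasoning
    for p in profiles:
        for combo in combos:
            feats = measure(np.array(p.means) + np.array(combo.effect), np.array(p.noise))
            _emit(rows, sid, 2, p, None, combo.mask, feats)
            sid += 1
    # Group 3: 80:20 ordered mixtures
    pairs = list(itertools.permutations(profiles, 2))
    for major, minor in pairs:
        feats = mix_features(major, minor, 0.8, rng=rng, noise_factor=cfg.mix_noise_factor)
        _emit(rows, sid, 3, major, minor, no_seasoning, feats)
        sid += 1
    # Group 4: mixtures with seasoning
    for major, minor in pairs:
        base = 0.8 * np.array(major.means) + 0.2 * np.array(minor.means)
        for combo in combos:
            feats = measure(
                base + np.array(combo.effect), np.array(major.noise), cfg.mix_noise_factor
            )
            _emit(rows, sid, 4, major, minor, combo.mask, feats)
            sid += 1

    df = pd.DataFrame(rows)
    assert len(df) == sum(GROUP_SIZES.values())
    return df


def split(
    df: pd.DataFrame, train_fraction: float = 0.6, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded, class-stratified train/test partition.

    Per-class training counts follow the largest-remainder rule so the total
    equals ``round(train_fraction * N)`` and every class is within one sample
    of its exact share.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_total = len(df)
    target_train = int(round(train_fraction * n_total))
    labels = df["label"].to_numpy()
    class_ids = sorted(set(labels.tolist()))
    shares = {c: train_fraction * int(np.sum(labels == c)) for c in class_ids}
    base = {c: int(np.floor(shares[c])) for c in class_ids}
    leftover = target_train - sum(base.values())
    order = sorted(class_ids, key=lambda c: (-(shares[c] - base[c]), c))
    for c in order[:leftover]:
        base[c] += 1
    train_mask = np.zeros(n_total, dtype=bool)
    for c in class_ids:
        idx = np.flatnonzero(labels == c)
        chosen = rng.permutation(idx)[: base[c]]
        train_mask[chosen] = True
    return df[train_mask].reset_index(drop=True), df[~train_mask].reset_index(drop=True)
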