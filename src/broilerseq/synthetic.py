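"""Synthetic flock behavior: condition-dependent semi-Markov bout streams.

The generator emulates the statistical structure the study design assumes,
so mining and reporting can be exercised end to end with no download:

* a behavior-transition matrix over the 13-code ethogram (self-transitions
  zero) with motif boosts for the feeding/exploration chains seen in
  broilers (Ld->P, P<->F, E->W, W->D/F);
* per-behavior dwell times drawn as ``min_bout_s + Exponential(mean)``,
  divided by an ``activity_scale`` so that heat-stressed flocks dwell
  longer and emit fewer behavioral events per window;
* environment closure — the explore behavior ``Ex`` exists only in
  enriched presets — and heat signatures: lying laterally ``Ll`` is
  reachable only under heat, with the St->Ll transition strongly elevated
  in the non-enriched heat preset and damped in the enriched one.

Defaults target roughly 10 events per 5-min window (about 140 events per
broiler-day across 14 windows) for a 10-broiler flock. Presets reproduce
the *direction* of the condition contrasts, not magnitudes: no raw data
exists to fit them against.

:func:`plant_pattern` splices a chosen pattern into a chosen fraction of
broilers for recovery testing with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import CapacityError, InvalidPresetError
from .ethogram import load_default_ethogram, validate_code
from .patterns import Pattern
from .sequence_db import Bout

__all__ = [
    "CONDITION_LABELS",
    "ConditionPreset",
    "SimConfig",
    "default_presets",
    "simulate_flock",
    "plant_pattern",
    "write_presets_yaml",
    "load_presets_yaml",
]

CONDITION_LABELS: tuple[str, ...] = (
    "thermoneutral_plain",
    "thermoneutral_enriched",
    "heat_plain",
    "heat_enriched",
)

# Relative propensity of each behavior per thermal condition. Zero removes a
# behavior from the emission alphabet (Ll is a heat posture only).
_PROPENSITY: dict[str, dict[str, float]] = {
    "thermoneutral": {
        "Ld": 3.0, "P": 2.5, "F": 2.5, "W": 2.0, "E": 1.5, "D": 1.0,
        "Sf": 0.5, "St": 0.5, "R": 0.15, "Db": 0.2, "Wf": 0.15,
        "Ex": 1.0, "Ll": 0.0,
    },
    "heat": {
        "Ld": 3.5, "P": 2.0, "F": 1.2, "W": 1.2, "E": 0.8, "D": 1.5,
        "Sf": 0.3, "St": 0.8, "R": 0.05, "Db": 0.05, "Wf": 0.1,
        "Ex": 0.5, "Ll": 1.5,
    },
}

# Mean of the exponential dwell component, seconds (the 10-s floor is added
# on top). Weighted by propensity this gives ~20 s, i.e. ~30 s mean dwell
# and ~10 events per 5-min window at activity_scale 1.
_DWELL_MEAN_S: dict[str, float] = {
    "Ld": 38.0, "P": 22.0, "F": 22.0, "W": 13.0, "E": 25.0, "D": 15.0,
    "Sf": 10.0, "St": 10.0, "R": 6.0, "Db": 25.0, "Wf": 6.0,
    "Ex": 22.0, "Ll": 50.0,
}

# Multiplicative boosts for behavior chains broilers favor.
_MOTIF_BOOST: dict[tuple[str, str], float] = {
    ("Ld", "P"): 2.0,
    ("P", "F"): 2.0,
    ("F", "P"): 2.0,
    ("E", "W"): 2.0,
    ("W", "D"): 1.5,
    ("W", "F"): 1.5,
}

_ACTIVITY_SCALE = {"thermoneutral": 1.0, "heat": 0.55}

# Stretch-then-lie-laterally: the heat-dissipation signature, strongly
# elevated without enrichment, damped with it.
_ST_LL_BOOST = {"heat_plain": 6.0, "heat_enriched": 0.5}


@dataclass(frozen=True)
class ConditionPreset:
    """Semi-Markov generator parameters for one housing x thermal condition."""

    label: str
    transition_weights: Mapping[str, Mapping[str, float]]
    dwell_mean_s: Mapping[str, float]
    activity_scale: float
    allowed_codes: frozenset[str]

    @property
    def enriched(self) -> bool:
        return "enriched" in self.label

    def emission_codes(self) -> tuple[str, ...]:
        """Codes that can actually occur: allowed and reachable."""
        eth = load_default_ethogram()
        reachable = {t for row in self.transition_weights.values() for t, w in row.items() if w > 0}
        reachable |= {c for c, row in self.transition_weights.items() if row}
        return tuple(c for c in eth.codes if c in self.allowed_codes and c in reachable)


def _make_preset(label: str) -> ConditionPreset:
    thermal = "heat" if label.startswith("heat") else "thermoneutral"
    enriched = label.endswith("enriched")
    eth = load_default_ethogram()
    prop = dict(_PROPENSITY[thermal])
    allowed = frozenset(
        c for c in eth.codes if enriched or not eth[c].enriched_only
    )
    active = [c for c in eth.codes if c in allowed and prop.get(c, 0.0) > 0.0]
    weights: dict[str, dict[str, float]] = {}
    for src in active:
        row: dict[str, float] = {}
        for dst in active:
            if dst == src:
                continue  # self-transition weight 0: a dwell ends with a switch
            w = prop[dst] * _MOTIF_BOOST.get((src, dst), 1.0)
            if src == "St" and dst == "Ll":
                w *= _ST_LL_BOOST.get(label, 1.0)
            if w > 0:
                row[dst] = w
        weights[src] = row
    return ConditionPreset(
        label=label,
        transition_weights=weights,
        dwell_mean_s=dict(_DWELL_MEAN_S),
        activity_scale=_ACTIVITY_SCALE[thermal],
        allowed_codes=allowed,
    )


def default_presets() -> dict[str, ConditionPreset]:
    """The four named condition presets."""
    return {label: _make_preset(label) for label in CONDITION_LABELS}


@dataclass(frozen=True)
class SimConfig:
    """Flock-simulation parameters; defaults mirror the study design:
    10 broilers per condition, 14 five-minute windows, 10-s bout floor."""

    preset: ConditionPreset
    n_broilers: int = 10
    n_windows: int = 14
    window_s: float = 300.0
    min_bout_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_broilers < 1:
            raise ValueError("n_broilers must be >= 1")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.window_s < self.min_bout_s:
            raise ValueError("window_s must be >= min_bout_s")

    def scaled(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _validate_preset(preset: ConditionPreset) -> None:
    eth = load_default_ethogram()
    for code in preset.allowed_codes:
        if code not in eth:
            raise InvalidPresetError(f"preset {preset.label!r}: unknown code {code!r}")
    if not preset.enriched:
        for code in eth.enriched_only_codes():
            if code in preset.allowed_codes:
                raise InvalidPresetError(
                    f"preset {preset.label!r} is non-enriched but allows {code!r}"
                )
    for src, row in preset.transition_weights.items():
        total = sum(w for dst, w in row.items() if dst in preset.allowed_codes and dst != src)
        if total <= 0:
            raise InvalidPresetError(
                f"preset {preset.label!r}: transition row for {src!r} is unnormalizable"
            )
        if row.get(src, 0.0) > 0:
            raise InvalidPresetError(
                f"preset {preset.label!r}: self-transition weight for {src!r} must be 0"
            )


def simulate_flock(config: SimConfig) -> list[Bout]:
    """Simulate one flock: a seeded semi-Markov bout stream per broiler.

    Each window starts a fresh walk: an initial behavior drawn from the
    preset's stationary propensities, then alternating dwell draws
    (exponential with a ``min_bout_s`` floor, scaled by
    ``dwell_mean_s / activity_scale``) and transitions from the current
    row of the weight matrix. The final bout of a window is truncated at
    the window boundary; windowing later discards it if the remainder is
    below the bout floor. Identical config and seed give identical output.
    """
    preset = config.preset
    _validate_preset(preset)
    rng = np.random.default_rng(config.seed)
    codes = preset.emission_codes()
    if not codes:
        raise InvalidPresetError(f"preset {preset.label!r} has no emittable codes")
    index = {c: i for i, c in enumerate(codes)}

    init_w = np.array([sum(row.get(c, 0.0) for row in preset.transition_weights.values())
                       for c in codes])
    if init_w.sum() <= 0:
        raise InvalidPresetError(f"preset {preset.label!r}: no positive transition weights")
    init_p = init_w / init_w.sum()

    rows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for src in codes:
        row = preset.transition_weights.get(src, {})
        targets = np.array([index[dst] for dst, w in row.items() if w > 0 and dst in index])
        probs = np.array([w for dst, w in row.items() if w > 0 and dst in index], dtype=float)
        rows[src] = (targets, probs / probs.sum())

    day = 22 if preset.label.startswith("heat") else 21
    width = len(str(config.n_broilers))
    bouts: list[Bout] = []
    for b in range(config.n_broilers):
        bid = f"broiler_{b + 1:0{width}d}"
        for w in range(config.n_windows):
            t = 0.0
            code = codes[rng.choice(len(codes), p=init_p)]
            while True:
                dwell = config.min_bout_s + rng.exponential(
                    preset.dwell_mean_s[code] / preset.activity_scale
                )
                if t + dwell >= config.window_s:
                    remainder = config.window_s - t
                    if remainder > 1e-9:
                        bouts.append(Bout(bid, preset.label, w, t, remainder, code, day))
                    break
                bouts.append(Bout(bid, preset.label, w, t, dwell, code, day))
                t += dwell
                targets, probs = rows[code]
                code = codes[targets[rng.choice(len(targets), p=probs)]]
    return bouts


def plant_pattern(
    bouts: Iterable[Bout],
    pattern: Pattern,
    carrier_fraction: float,
    config: SimConfig,
    seed: int,
) -> list[Bout]:
    """Splice ``pattern`` into ``ceil(carrier_fraction * n_broilers)`` broilers.

    For each carrier, the pattern's elements are inserted at the start of
    distinct, increasing windows as ``min_bout_s`` bouts; pre-existing
    bouts in those windows are displaced later in time and truncated at
    the window boundary (dropped when fully displaced). After windowing,
    every carrier's sequence contains the pattern.
    """
    if not (0.0 < carrier_fraction <= 1.0):
        raise ValueError(f"carrier_fraction must lie in (0, 1], got {carrier_fraction}")
    eth = load_default_ethogram()
    for code in sorted(pattern.codes):
        validate_code(code, eth, enriched=config.preset.enriched)
    if pattern.size > config.n_windows:
        raise CapacityError(
            f"pattern has {pattern.size} elements but only {config.n_windows} windows exist"
        )
    for el in pattern.elements:
        if len(el) * config.min_bout_s > config.window_s + 1e-9:
            raise CapacityError(
                f"element {{{','.join(el)}}} needs {len(el)} x {config.min_bout_s:g} s "
                f"but the window is {config.window_s:g} s"
            )

    bouts = list(bouts)
    ids = sorted({b.broiler_id for b in bouts})
    n_carriers = ceil(carrier_fraction * config.n_broilers)
    rng = np.random.default_rng(seed)
    carriers = sorted(
        np.asarray(ids, dtype=object)[
            rng.choice(len(ids), size=min(n_carriers, len(ids)), replace=False)
        ]
    )

    by_key: dict[tuple[str, int], list[Bout]] = {}
    passthrough: list[Bout] = []
    carrier_set = set(carriers)
    target_windows: dict[str, list[int]] = {
        bid: sorted(int(w) for w in rng.choice(config.n_windows, size=pattern.size, replace=False))
        for bid in carriers
    }
    for b in bouts:
        if b.broiler_id in carrier_set and b.window_index in target_windows[b.broiler_id]:
            by_key.setdefault((b.broiler_id, b.window_index), []).append(b)
        else:
            passthrough.append(b)

    planted: list[Bout] = []
    for bid in carriers:
        sample = next((b for b in bouts if b.broiler_id == bid), None)
        condition_id = sample.condition_id if sample else config.preset.label
        day = sample.day if sample else None
        for element, w in zip(pattern.elements, target_windows[bid]):
            offset = len(element) * config.min_bout_s
            for i, code in enumerate(element):
                planted.append(
                    Bout(bid, condition_id, w, i * config.min_bout_s, config.min_bout_s, code, day)
                )
            for b in sorted(by_key.get((bid, w), ()), key=lambda b: b.onset_s):
                onset = b.onset_s + offset
                if onset >= config.window_s - 1e-9:
                    continue
                duration = min(b.duration_s, config.window_s - onset)
                planted.append(
                    Bout(bid, b.condition_id, w, onset, duration, b.behavior, b.day)
                )

    out = passthrough + planted
    out.sort(key=lambda b: (b.broiler_id, b.window_index, b.onset_s))
    return out


# ---------------------------------------------------------------------------
# Preset registry I/O (YAML)
# ---------------------------------------------------------------------------


def write_presets_yaml(presets: Mapping[str, ConditionPreset], path: str | Path) -> None:
    doc = {
        label: {
            "activity_scale": p.activity_scale,
            "allowed_codes": sorted(p.allowed_codes),
            "dwell_mean_s": dict(p.dwell_mean_s),
            "transition_weights": {s: dict(r) for s, r in p.transition_weights.items()},
        }
        for label, p in presets.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_presets_yaml(path: str | Path) -> dict[str, ConditionPreset]:
    doc = yaml.safe_load(Path(path).read_text())
    presets = {}
    for label, raw in doc.items():
        presets[label] = ConditionPreset(
            label=label,
            transition_weights={s: dict(r) for s, r in raw["transition_weights"].items()},
            dwell_mean_s=dict(raw["dwell_mean_s"]),
            activity_scale=float(raw["activity_scale"]),
            allowed_codes=frozenset(raw["allowed_codes"]),
        )
    return presets
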