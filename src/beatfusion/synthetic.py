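"""Synthetic heartbeat generator with class-distinct P-QRS-T morphology.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T waves) on the unit
interval, sampled at a fixed window length, with per-beat timing jitter and
additive Gaussian noise.  The five class templates differ in morphology the
way the AAMI classes coarsely do — e.g. ventricular ectopic beats (V) have a
widened QRS and no P wave, supraventricular ectopic beats (S) an early P
wave — so downstream encoders, losses and metrics can be exercised on a
learnable, imbalanced five-class problem with no external data.

This is deliberately not a physiological simulator: beats are independent
(no rhythm context), single-lead, and noise is white Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import CLASSES, BeatSegment, LabeledDataset

__all__ = [
    "WAVES",
    "BeatTemplate",
    "default_templates",
    "table2_like_counts",
    "generate_beat",
    "generate_dataset",
    "save_fixture",
    "load_fixture",
]

#: Canonical wave order within one cardiac cycle.
WAVES: tuple[str, ...] = ("P", "Q", "R", "S", "T")

#: Class proportions emulating the heavy N-dominance of the MIT-BIH beat
#: inventory (N/S/V/F/Q); normalized before use.
TABLE2_LIKE_PROPORTIONS: dict[str, float] = {"N": 0.84, "S": 0.026, "V": 0.067, "F": 0.007, "Q": 0.074}


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat class.

    wave_params maps each wave to (center, width, amplitude): center and
    width are fractions of the beat window, amplitude is in dimensionless
    mV-like units.  noise_sd is the additive white-noise level; jitter_sd
    shifts all wave centers together per beat (beat-alignment jitter).
    When random_amplitudes is set, every wave's amplitude is redrawn
    uniformly from random_amp_range per beat (low-structure "unknown" beats).
    """

    class_label: str
    wave_params: dict[str, tuple[float, float, float]]
    noise_sd: float = 0.05
    jitter_sd: float = 0.01
    random_amplitudes: bool = False
    random_amp_range: tuple[float, float] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        centers = []
        for wave in WAVES:
            if wave not in self.wave_params:
                continue
            center, width, _amp = self.wave_params[wave]
            if width <= 0:
                raise ValueError(f"wave {wave}: width must be > 0")
            centers.append(center)
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly increasing in P<Q<R<S<T order")


def default_templates(noise_sd: float = 0.05, jitter_sd: float = 0.01) -> dict[str, BeatTemplate]:
    """One template per class, differing in at least one wave parameter.

    N is a canonical P-QRS-T; S shifts the P wave 0.08 earlier (premature
    atrial activation); V triples the R width and removes the P wave (wide
    QRS, no atrial wave); F averages the N and V parameters (fusion beat);
    Q draws all amplitudes uniformly per beat (artifact-like).
    """
    n_waves = {
        "P": (0.20, 0.030, 0.18),
        "Q": (0.44, 0.015, -0.15),
        "R": (0.50, 0.025, 1.00),
        "S": (0.56, 0.015, -0.25),
        "T": (0.75, 0.060, 0.35),
    }
    v_waves = {
        "P": (0.20, 0.030, 0.00),
        "Q": (0.44, 0.030, -0.30),
        "R": (0.50, 0.075, 0.90),
        "S": (0.58, 0.030, -0.45),
        "T": (0.78, 0.080, -0.30),
    }
    f_waves = {
        w: tuple((np.array(n_waves[w]) + np.array(v_waves[w])) / 2.0) for w in WAVES
    }
    s_waves = dict(n_waves)
    s_waves["P"] = (0.20 - 0.08, 0.030, 0.18)
    common = dict(noise_sd=noise_sd, jitter_sd=jitter_sd)
    return {
        "N": BeatTemplate("N", n_waves, **common),
        "S": BeatTemplate("S", s_waves, **common),
        "V": BeatTemplate("V", v_waves, **common),
        "F": BeatTemplate("F", f_waves, **common),
        "Q": BeatTemplate("Q", n_waves, random_amplitudes=True, **common),
    }


def table2_like_counts(total: int) -> dict[str, int]:
    """Allocate `total` beats to N/S/V/F/Q by the imbalance preset.

    Proportions are normalized and allocated by largest remainder so the
    counts sum to `total` exactly.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    weights = np.array([TABLE2_LIKE_PROPORTIONS[c] for c in CLASSES])
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    order = np.argsort(-(raw - base))
    for i in order[: total - base.sum()]:
        base[i] += 1
    return dict(zip(CLASSES, (int(v) for v in base)))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_beat(template: BeatTemplate, window_len: int = 360, rng_seed=0) -> BeatSegment:
    """Render one beat: five Gaussian bumps + jitter + white noise.

    The window is sampled at t = i / window_len for i in [0, window_len);
    each wave contributes amplitude · exp(−(t − center)² / (2 width²)).
    The same seed yields a bit-identical beat.
    """
    if window_len < 32:
        raise ValueError("window_len must be >= 32")
    rng = _as_rng(rng_seed)
    t = np.arange(window_len) / window_len
    jitter = rng.normal(0.0, template.jitter_sd) if template.jitter_sd > 0 else 0.0
    amplitudes = {w: p[2] for w, p in template.wave_params.items()}
    if template.random_amplitudes:
        lo, hi = template.random_amp_range
        for w in template.wave_params:
            amplitudes[w] = rng.uniform(lo, hi)
    x = np.zeros(window_len)
    for wave, (center, width, _amp) in template.wave_params.items():
        x += amplitudes[wave] * np.exp(-((t - center - jitter) ** 2) / (2.0 * width**2))
    if template.noise_sd > 0:
        x = x + rng.normal(0.0, template.noise_sd, size=window_len)
    return BeatSegment(x, label=template.class_label)


def generate_dataset(
    class_counts: dict[str, int],
    templates: dict[str, BeatTemplate] | None = None,
    window_len: int = 360,
    rng_seed: int = 0,
) -> LabeledDataset:
    """Generate Σ counts labeled beats, deterministically under the seed."""
    if templates is None:
        templates = default_templates()
    for label, count in class_counts.items():
        if count < 0:
            raise ValueError(f"count for class {label!r} must be >= 0")
        if count > 0 and label not in templates:
            raise KeyError(f"no template for requested class {label!r}")
    rng = _as_rng(rng_seed)
    vocab = [c for c in CLASSES if c in class_counts] or list(class_counts)
    beats: list[BeatSegment] = []
    for label in vocab:
        tpl = templates.get(label)
        for _ in range(class_counts.get(label, 0)):
            beats.append(generate_beat(tpl, window_len=window_len, rng_seed=rng))
    return LabeledDataset(beats, class_vocabulary=vocab)


# -- fixture persistence ---------------------------------------------------------


def save_fixture(dataset: LabeledDataset, header_path, matrix_path, rng_seed: int | None = None) -> None:
    """Persist a dataset as plain-text header + dense matrix files."""
    window_len = dataset.beats[0].samples.size if dataset.beats else 0
    with open(header_path, "w") as fh:
        fh.write(f"window_len: {window_len}\n")
        fh.write(f"n_beats: {len(dataset)}\n")
        fh.write(f"class_vocabulary: {','.join(dataset.class_vocabulary)}\n")
        fh.write(f"seed: {'' if rng_seed is None else rng_seed}\n")
        fh.write("labels: " + ",".join(b.label for b in dataset.beats) + "\n")
    X, _ = dataset.to_arrays()
    np.savetxt(matrix_path, X, fmt="%.10g")


def load_fixture(header_path, matrix_path) -> LabeledDataset:
    header: dict[str, str] = {}
    with open(header_path) as fh:
        for line in fh:
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
    vocab = header["class_vocabulary"].split(",")
    labels = header["labels"].split(",") if header["labels"] else []
    X = np.loadtxt(matrix_path, ndmin=2)
    if X.shape[0] != len(labels):
        raise ValueError("matrix rows do not match header labels")
    beats = [BeatSegment(row, label=lab) for row, lab in zip(X, labels)]
    return LabeledDataset(beats, class_vocabulary=vocab)
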