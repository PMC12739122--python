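"""Beat-level ECG preprocessing: filtering, normalization, segmentation,
annotation-symbol mapping, train/val/test splitting, and augmentation.

The pipeline mirrors standard practice for the MIT-BIH arrhythmia database:
a 0.5–50 Hz zero-phase band-pass removes baseline drift and mains
interference, beats are cut as fixed windows centered on the annotated
R-peak, each beat is z-scored individually, and beat annotation symbols are
collapsed onto the five AAMI-style classes N/S/V/F/Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Default class vocabulary (AAMI-style five-class scheme).
CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

#: Beat annotation symbol -> class label. N: normal, bundle-branch block and
#: escape beats; S: supraventricular ectopic; V: ventricular ectopic;
#: F: fusion of ventricular and normal; Q: unclassifiable/artifact.
SYMBOL_TO_CLASS: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "f": "Q", "u": "Q",
}

SPLITS = ("train", "val", "test", "unassigned")


class UnmappedSymbolError(KeyError):
    """Raised for a beat annotation symbol outside the five-class mapping."""


class DegenerateInputError(ValueError):
    """Raised when an input is constant/empty where variation is required."""


@dataclass
class BeatSegment:
    """One fixed-length, preprocessed single-lead beat window."""

    samples: np.ndarray
    label: str
    source_record: str | None = None
    r_peak_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("beat samples must be a 1-D vector")


class LabeledDataset:
    """Ordered collection of beats plus the class vocabulary and split tags."""

    def __init__(
        self,
        beats: list[BeatSegment],
        class_vocabulary: tuple[str, ...] | list[str] = CLASSES,
        split_tags: list[str] | None = None,
    ):
        self.beats = list(beats)
        self.class_vocabulary = list(class_vocabulary)
        self.split_tags = list(split_tags) if split_tags is not None else ["unassigned"] * len(self.beats)
        if len(self.split_tags) != len(self.beats):
            raise ValueError("one split tag per beat required")
        for tag in self.split_tags:
            if tag not in SPLITS:
                raise ValueError(f"unknown split tag {tag!r}")
        for b in self.beats:
            if b.label not in self.class_vocabulary:
                raise ValueError(f"label {b.label!r} not in class vocabulary {self.class_vocabulary}")

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)

    def label_counts(self, split: str | None = None) -> dict[str, int]:
        counts = {c: 0 for c in self.class_vocabulary}
        for b, tag in zip(self.beats, self.split_tags):
            if split is None or tag == split:
                counts[b.label] += 1
        return counts

    def subset(self, split: str) -> "LabeledDataset":
        beats = [b for b, t in zip(self.beats, self.split_tags) if t == split]
        return LabeledDataset(beats, self.class_vocabulary, [split] * len(beats))

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack beats into (n, window_len) and integer labels (n,)."""
        if not self.beats:
            vocab_index = {}
            return np.zeros((0, 0)), np.zeros(0, dtype=np.int64)
        X = np.stack([b.samples for b in self.beats])
        vocab_index = {c: i for i, c in enumerate(self.class_vocabulary)}
        y = np.array([vocab_index[b.label] for b in self.beats], dtype=np.int64)
        return X, y

    def write_csv(self, path) -> None:
        """One beat per row; last column is the class label."""
        with open(path, "w") as fh:
            for b in self.beats:
                fh.write(",".join(f"{v:.10g}" for v in b.samples) + f",{b.label}\n")

    def write_split_manifest(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("beat_index\tsplit\n")
            for i, tag in enumerate(self.split_tags):
                fh.write(f"{i}\t{tag}\n")


def read_csv_dataset(path, class_vocabulary: tuple[str, ...] | list[str] = CLASSES) -> LabeledDataset:
    """Read the one-beat-per-row CSV written by :meth:`LabeledDataset.write_csv`."""
    beats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            *values, label = line.split(",")
            beats.append(BeatSegment(np.array([float(v) for v in values]), label=label))
    return LabeledDataset(beats, class_vocabulary)


# -- preprocessing -------------------------------------------------------------


def bandpass_filter(x: np.ndarray, fs: float, low: float = 0.5, high: float = 50.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass (4th order, applied forward-backward).

    Removes baseline wander below `low` and high-frequency noise above
    `high` while leaving the pass band at unit gain and zero phase shift.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"need 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    x = np.asarray(x, dtype=np.float64)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    # the low corner settles slowly; pad by ~3 of its time constants with an
    # even reflection so edge transients do not leak into the record
    padlen = min(x.size - 1, int(3 * fs / low))
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to zero mean and unit sample standard deviation (ddof=1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least two samples to normalize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant signal has zero variance")
    return (x - x.mean()) / sd


def map_annotation_symbol(symbol: str) -> str:
    """Map a single-character beat annotation to its five-class label."""
    if not isinstance(symbol, str) or len(symbol) != 1:
        raise ValueError("annotation symbol must be a single character")
    try:
        return SYMBOL_TO_CLASS[symbol]
    except KeyError:
        raise UnmappedSymbolError(symbol) from None


@dataclass
class SegmentationResult:
    """Segments plus skip accounting; len()/iteration yield the segments."""

    segments: list[BeatSegment] = field(default_factory=list)
    n_skipped_boundary: int = 0
    n_skipped_unmapped: int = 0

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def segment_beats(
    x: np.ndarray,
    r_peaks: np.ndarray,
    symbols: list[str],
    window_len: int = 360,
    source_record: str | None = None,
) -> SegmentationResult:
    """Cut one half-open window [r − ⌊w/2⌋, r + ⌈w/2⌉) per annotated R-peak.

    Beats whose window would cross a record boundary are skipped, as are
    annotations whose symbol is not a mappable beat symbol (rhythm labels
    etc.); both skip counts are reported so callers can verify that
    segments + skips = annotations.
    """
    x = np.asarray(x, dtype=np.float64)
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if len(r_peaks) != len(symbols):
        raise ValueError("r_peaks and symbols must have equal length")
    if len(r_peaks) > 1 and np.any(np.diff(r_peaks) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    if window_len > x.size:
        raise ValueError("window_len exceeds signal length")
    half_lo = window_len // 2
    half_hi = window_len - half_lo
    result = SegmentationResult()
    for r, sym in zip(r_peaks, symbols):
        try:
            label = map_annotation_symbol(sym)
        except UnmappedSymbolError:
            result.n_skipped_unmapped += 1
            continue
        lo, hi = int(r) - half_lo, int(r) + half_hi
        if lo < 0 or hi > x.size:
            result.n_skipped_boundary += 1
            continue
        result.segments.append(
            BeatSegment(x[lo:hi].copy(), label=label, source_record=source_record, r_peak_index=int(r))
        )
    if result.n_skipped_unmapped:
        logger.info(
            "segment_beats: skipped %d unmapped annotation(s) in %s",
            result.n_skipped_unmapped,
            source_record or "<record>",
        )
    return result


# -- splitting ------------------------------------------------------------------


def _allocate(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items to the three splits."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    remainder = n - sum(base)
    order = sorted(range(3), key=lambda i: (raw[i] - base[i], -i), reverse=True)
    for i in order[:remainder]:
        base[i] += 1
    return base


def split_dataset(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    rng_seed: int = 0,
    stratified: bool = True,
) -> LabeledDataset:
    """Assign train/val/test tags (70/10/20 by default), optionally per class.

    Stratified mode allocates each class by largest remainder, so every
    per-class split count is within one beat of count × fraction. A class
    with fewer beats than splits is kept whole in train (with a warning).
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(rng_seed)
    n = len(dataset)
    tags = np.array(["unassigned"] * n, dtype=object)
    if stratified:
        labels = np.array([b.label for b in dataset.beats])
        for cls in dataset.class_vocabulary:
            idx = np.flatnonzero(labels == cls)
            if idx.size == 0:
                continue
            if idx.size < 3:
                logger.warning("class %s has %d beat(s) < 3 splits; kept whole in train", cls, idx.size)
                tags[idx] = "train"
                continue
            rng.shuffle(idx)
            n_tr, n_va, n_te = _allocate(idx.size, fractions)
            tags[idx[:n_tr]] = "train"
            tags[idx[n_tr : n_tr + n_va]] = "val"
            tags[idx[n_tr + n_va :]] = "test"
    else:
        idx = rng.permutation(n)
        n_tr, n_va, n_te = _allocate(n, fractions)
        tags[idx[:n_tr]] = "train"
        tags[idx[n_tr : n_tr + n_va]] = "val"
        tags[idx[n_tr + n_va :]] = "test"
    return LabeledDataset(dataset.beats, dataset.class_vocabulary, list(tags))


# -- augmentation ---------------------------------------------------------------


def augment_beat(beat: BeatSegment, stretch_factor: float = 1.0, scale_factor: float = 1.0) -> BeatSegment:
    """Time-stretch then amplitude-scale one beat, preserving window length.

    The beat is linearly resampled to stretch_factor × its duration, then
    center-cropped (stretch > 1) or zero-padded (stretch < 1) back to the
    original window, and finally multiplied by scale_factor.
    """
    if not (0.5 <= stretch_factor <= 2.0):
        raise ValueError("stretch_factor must lie in [0.5, 2]")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    x = beat.samples
    L = x.size
    new_len = max(2, int(round(L * stretch_factor)))
    if new_len == L:
        y = x.copy()
    else:
        y = np.interp(np.linspace(0.0, L - 1.0, new_len), np.arange(L), x)
    if new_len > L:
        lo = (new_len - L) // 2
        y = y[lo : lo + L]
    elif new_len < L:
        pad_lo = (L - new_len) // 2
        y = np.concatenate([np.zeros(pad_lo), y, np.zeros(L - new_len - pad_lo)])
    return BeatSegment(
        y * scale_factor,
        label=beat.label,
        source_record=beat.source_record,
        r_peak_index=beat.r_peak_index,
    )
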