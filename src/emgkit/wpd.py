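"""Wavelet-packet decomposition and per-subband statistical features.

Each frame is pushed through a full dyadic analysis filter bank: both the
approximation and the detail branch are split again at every level, so a
level-4 transform of a 2048-sample frame yields 16 terminal subbands of 128
coefficients each (periodic extension).  Six statistics summarise every
subband's coefficient distribution:

* mean absolute value          (1/M) Σ |y_j|
* average power                (1/M) Σ y_j²
* standard deviation           sqrt((1/M) Σ (y_j − ȳ)²)   (population form)
* skewness                     (1/M) Σ ((y_j − ȳ)/σ)³
* kurtosis                     (1/M) Σ ((y_j − ȳ)/σ)⁴     (raw, no −3)
* adjacent-subband ratio       Σ|y_j| of band i / Σ|z_j| of band i+1

"Adjacent" means frequency-adjacent: terminal nodes are put in increasing
frequency order (the Gray-code permutation of the natural filter-bank
order) before ratios are formed.  Degenerate cases (zero variance, zero
ratio denominator) yield 0 with a logged warning — features stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .errors import (
    ConfigurationError,
    DecompositionError,
    ReconstructionError,
    TableError,
)
from .io import Frame

logger = logging.getLogger(__name__)

_MODE_MAP = {"periodic": "periodization", "symmetric": "symmetric", "zero": "zero"}
STAT_NAMES = ("meanabs", "avgpower", "std", "skewness", "kurtosis")


@dataclass(frozen=True)
class WpdConfig:
    """Wavelet-packet settings.

    ``statistics`` restricts the per-subband statistic set (default all
    five); ``include_ratios`` toggles the adjacent-band ratio features.
    """

    wavelet_name: str = "db4"
    level: int = 4
    extension_mode: str = "periodic"
    subband_set: str = "terminal"  # or "all_nodes"
    ordering: str = "frequency"  # or "natural"
    statistics: tuple[str, ...] = STAT_NAMES
    include_ratios: bool = True

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ConfigurationError("level must be >= 1")
        if self.extension_mode not in _MODE_MAP:
            raise ConfigurationError(
                f"extension_mode must be one of {sorted(_MODE_MAP)}"
            )
        if self.subband_set not in ("terminal", "all_nodes"):
            raise ConfigurationError("subband_set must be 'terminal' or 'all_nodes'")
        if self.ordering not in ("frequency", "natural"):
            raise ConfigurationError("ordering must be 'frequency' or 'natural'")
        unknown = set(self.statistics) - set(STAT_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown statistics: {sorted(unknown)}")
        try:
            self.wavelet()
        except ValueError as exc:
            raise ConfigurationError(f"unknown wavelet {self.wavelet_name!r}") from exc

    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.wavelet_name)

    @property
    def pywt_mode(self) -> str:
        return _MODE_MAP[self.extension_mode]


@dataclass
class SubbandCoefficients:
    """Coefficients of one wavelet-packet node."""

    level: int
    index: int  # position within its level under the configured ordering
    coefficients: np.ndarray

    @property
    def M(self) -> int:
        return len(self.coefficients)


def frequency_order(level: int) -> list[int]:
    """Natural (filter-bank) node indices listed in increasing frequency.

    At each descent, children of a node sitting at an odd frequency
    position appear frequency-reversed (the classic Gray-code ordering of
    a wavelet-packet tree).
    """
    order = [0]
    for _ in range(level):
        nxt: list[int] = []
        for pos, node in enumerate(order):
            a, d = 2 * node, 2 * node + 1
            nxt.extend((a, d) if pos % 2 == 0 else (d, a))
        order = nxt
    return order


def _decompose_matrix(frames: np.ndarray, config: WpdConfig) -> list[list[np.ndarray]]:
    """Full packet tree of a (n_frames, frame_len) matrix.

    Returns per-level lists of node coefficient matrices in *natural*
    order; levels[0] is the input itself.
    """
    wavelet = config.wavelet()
    mode = config.pywt_mode
    levels = [[frames]]
    for _ in range(config.level):
        nxt: list[np.ndarray] = []
        for node in levels[-1]:
            ca, cd = pywt.dwt(node, wavelet, mode=mode, axis=-1)
            nxt.extend((ca, cd))
        levels.append(nxt)
    return levels


def _check_frame(frame: np.ndarray, config: WpdConfig) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 1:
        raise DecompositionError("frame must be one-dimensional")
    n = len(frame)
    if n < 2**config.level:
        raise DecompositionError(
            f"frame of {n} samples too short for level {config.level}"
        )
    if config.extension_mode == "periodic" and n % (2**config.level) != 0:
        raise DecompositionError(
            f"periodic extension requires frame length divisible by 2^level "
            f"({n} % {2**config.level} != 0)"
        )
    return frame


def wpd_decompose(frame: np.ndarray, config: WpdConfig | None = None) -> list[SubbandCoefficients]:
    """Decompose one frame into its wavelet-packet subbands.

    With ``subband_set='terminal'`` the result is the 2^level leaf nodes
    (default ordering: increasing frequency).  With ``'all_nodes'`` every
    node of levels 1..level is returned, level-major.
    """
    config = config or WpdConfig()
    frame = _check_frame(frame, config)
    levels = _decompose_matrix(frame[None, :], config)
    out: list[SubbandCoefficients] = []
    level_range = (
        range(config.level, config.level + 1)
        if config.subband_set == "terminal"
        else range(1, config.level + 1)
    )
    for lev in level_range:
        nodes = levels[lev]
        order = frequency_order(lev) if config.ordering == "frequency" else range(len(nodes))
        for pos, nat in enumerate(order):
            out.append(SubbandCoefficients(lev, pos, nodes[nat][0]))
    return out


def wpd_reconstruct(subbands: list[SubbandCoefficients], config: WpdConfig | None = None) -> np.ndarray:
    """Invert a complete terminal decomposition (periodic mode only).

    Requires all 2^level terminal nodes under the configured ordering;
    raises :class:`ReconstructionError` otherwise.
    """
    config = config or WpdConfig()
    if config.extension_mode != "periodic":
        raise ReconstructionError(
            "exact reconstruction is supported for the periodic extension mode only"
        )
    n_nodes = 2**config.level
    terminal = [sb for sb in subbands if sb.level == config.level]
    if len(terminal) != n_nodes or {sb.index for sb in terminal} != set(range(n_nodes)):
        raise ReconstructionError(
            f"need the complete set of {n_nodes} terminal subbands at level {config.level}"
        )
    lengths = {sb.M for sb in terminal}
    if len(lengths) != 1:
        raise ReconstructionError("terminal subbands have inconsistent lengths")
    by_pos = {sb.index: np.asarray(sb.coefficients, dtype=float) for sb in terminal}
    order = (
        frequency_order(config.level)
        if config.ordering == "frequency"
        else list(range(n_nodes))
    )
    natural = [None] * n_nodes
    for pos, nat in enumerate(order):
        natural[nat] = by_pos[pos]
    wavelet, mode = config.wavelet(), config.pywt_mode
    nodes = natural
    for _ in range(config.level):
        nodes = [
            pywt.idwt(nodes[i], nodes[i + 1], wavelet, mode=mode)
            for i in range(0, len(nodes), 2)
        ]
    return nodes[0]


def _stats_matrix(coeffs: np.ndarray, statistics: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Vectorised subband statistics for a (n_frames, M) coefficient block."""
    meanabs = np.mean(np.abs(coeffs), axis=-1)
    avgpower = np.mean(coeffs**2, axis=-1)
    mean = np.mean(coeffs, axis=-1, keepdims=True)
    centered = coeffs - mean
    var = np.mean(centered**2, axis=-1)
    std = np.sqrt(var)
    degenerate = std == 0.0
    safe_std = np.where(degenerate, 1.0, std)
    z = centered / safe_std[..., None]
    skewness = np.where(degenerate, 0.0, np.mean(z**3, axis=-1))
    kurtosis = np.where(degenerate, 0.0, np.mean(z**4, axis=-1))
    if np.any(degenerate):
        logger.warning(
            "%d zero-variance subband(s): skewness/kurtosis set to 0",
            int(np.count_nonzero(degenerate)),
        )
    full = {
        "meanabs": meanabs,
        "avgpower": avgpower,
        "std": std,
        "skewness": skewness,
        "kurtosis": kurtosis,
    }
    return {name: full[name] for name in statistics}


def subband_stats(subband: SubbandCoefficients | np.ndarray) -> dict[str, float]:
    """The five distribution statistics of one subband's coefficients."""
    coeffs = (
        subband.coefficients if isinstance(subband, SubbandCoefficients) else np.asarray(subband, dtype=float)
    )
    if len(coeffs) < 1:
        raise DecompositionError("subband must contain at least one coefficient")
    stats = _stats_matrix(coeffs[None, :], STAT_NAMES)
    return {name: float(v[0]) for name, v in stats.items()}


def adjacent_ratios(subbands: list[SubbandCoefficients]) -> np.ndarray:
    """Ratio of summed absolute coefficients of each frequency-adjacent pair."""
    sums = np.array([np.sum(np.abs(sb.coefficients)) for sb in subbands])
    return _ratios_from_sums(sums[None, :])[0]


def _ratios_from_sums(sums: np.ndarray) -> np.ndarray:
    num, den = sums[..., :-1], sums[..., 1:]
    zero = den == 0.0
    if np.any(zero):
        logger.warning(
            "%d zero-denominator adjacent-band ratio(s) set to 0",
            int(np.count_nonzero(zero)),
        )
    return np.where(zero, 0.0, num / np.where(zero, 1.0, den))


@dataclass
class FeatureTable:
    """Instances × features matrix with class labels.

    ``groups`` records each row's source recording id (used for
    recording-grouped cross-validation); it may be empty.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    class_labels: tuple[str, ...]
    groups: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise TableError("feature matrix and labels are inconsistent")
        if self.X.shape[1] != len(self.feature_names):
            raise TableError("feature matrix and feature names are inconsistent")
        if not np.all(np.isfinite(self.X)):
            raise TableError("feature values must be finite")
        bad = set(self.labels) - set(self.class_labels)
        if bad:
            raise TableError(f"labels outside the class set: {sorted(map(str, bad))}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.labels
        return df


def extract_features(frames: list[Frame], config: WpdConfig | None = None) -> FeatureTable:
    """Build the feature table: one row per frame.

    With the defaults (level 4, terminal subbands, 5 statistics + ratios)
    each row has 16·5 + 15 = 95 features.  Column order is deterministic:
    per-subband statistics in frequency order, then the adjacent ratios.
    """
    config = config or WpdConfig()
    if len(frames) == 0:
        raise TableError("no frames to extract features from")
    lengths = {len(f) for f in frames}
    if len(lengths) != 1:
        raise TableError(f"mixed frame lengths: {sorted(lengths)}")
    matrix = np.stack([np.asarray(f.samples, dtype=float) for f in frames])
    _check_frame(matrix[0], config)
    levels = _decompose_matrix(matrix, config)

    blocks: list[tuple[str, np.ndarray]] = []  # (subband tag, (n, M) coeffs)
    level_range = (
        range(config.level, config.level + 1)
        if config.subband_set == "terminal"
        else range(1, config.level + 1)
    )
    for lev in level_range:
        nodes = levels[lev]
        order = frequency_order(lev) if config.ordering == "frequency" else range(len(nodes))
        for pos, nat in enumerate(order):
            blocks.append((f"L{lev}.S{pos:02d}", nodes[nat]))

    columns: list[np.ndarray] = []
    names: list[str] = []
    for tag, coeffs in blocks:
        stats = _stats_matrix(coeffs, config.statistics)
        for stat_name, values in stats.items():
            columns.append(values)
            names.append(f"{tag}.{stat_name}")
    if config.include_ratios:
        sums = np.stack(
            [np.sum(np.abs(coeffs), axis=-1) for _, coeffs in blocks], axis=-1
        )
        ratios = _ratios_from_sums(sums)
        for i in range(ratios.shape[-1]):
            columns.append(ratios[:, i])
            names.append(f"{blocks[i][0]}_{blocks[i + 1][0].split('.')[-1]}.ratio")

    labels = np.array([f.label for f in frames], dtype=object)
    class_labels = tuple(dict.fromkeys(labels))  # stable first-appearance order
    groups = np.array([f.source_id for f in frames], dtype=object)
    return FeatureTable(
        X=np.column_stack(columns),
        labels=labels,
        feature_names=names,
        class_labels=class_labels,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Feature-table serialization (CSV and ARFF)

def write_feature_table(table: FeatureTable, path, fmt: str | None = None) -> Path:
    """Write a feature table as CSV (label column last) or ARFF."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        table.to_frame().to_csv(path, index=False, float_format="%.17g")
    elif fmt == "arff":
        _write_arff(table, path)
    else:
        raise ConfigurationError(f"unknown feature-table format {fmt!r}")
    return path


def read_feature_table(path, fmt: str | None = None, class_labels: tuple[str, ...] | None = None) -> FeatureTable:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if "label" not in df.columns:
            raise TableError(f"{path}: feature CSV has no 'label' column")
        labels = df["label"].to_numpy(dtype=object)
        feats = df.drop(columns=["label"])
        return FeatureTable(
            X=feats.to_numpy(dtype=float),
            labels=labels,
            feature_names=list(feats.columns),
            class_labels=class_labels or tuple(dict.fromkeys(labels)),
        )
    if fmt == "arff":
        return _read_arff(path, class_labels=class_labels)
    raise ConfigurationError(f"unknown feature-table format {fmt!r}")


def _arff_quote(name: str) -> str:
    return f"'{name}'" if any(c in name for c in " ,{}%") else name


def _write_arff(table: FeatureTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("@relation emg-wpd-features\n\n")
        for name in table.feature_names:
            fh.write(f"@attribute {_arff_quote(name)} numeric\n")
        classes = ",".join(table.class_labels)
        fh.write(f"@attribute label {{{classes}}}\n\n@data\n")
        for row, label in zip(table.X, table.labels):
            fh.write(",".join(f"{v:.17g}" for v in row) + f",{label}\n")


def _read_arff(path: Path, class_labels: tuple[str, ...] | None = None) -> FeatureTable:
    names: list[str] = []
    classes: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                rest = line.split(None, 1)[1]
                if "{" in rest:
                    attr_name = rest.split("{")[0].strip().strip("'")
                    inner = rest[rest.index("{") + 1 : rest.rindex("}")]
                    classes = tuple(tok.strip() for tok in inner.split(","))
                    if attr_name != "label":
                        raise TableError(f"{path}: nominal attribute {attr_name!r} is not 'label'")
                else:
                    names.append(rest.split()[0].strip("'"))
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            if in_data:
                parts = line.split(",")
                rows.append([float(v) for v in parts[:-1]])
                labels.append(parts[-1].strip())
    if classes is None:
        raise TableError(f"{path}: ARFF file declares no nominal label attribute")
    return FeatureTable(
        X=np.array(rows, dtype=float),
        labels=np.array(labels, dtype=object),
        feature_names=names,
        class_labels=class_labels or classes,
    )
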