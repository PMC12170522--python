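"""Labeled spectra tables and chemometric preprocessing.

A spectra table is delimited text whose header row carries the wavelength
axis (numeric column names, nm) plus a label column and an optional sample-id
column.  The three row-wise transforms implemented here are the standard
chemometrics trio: standard normal variate (SNV), multiplicative scatter
correction (MSC), and Savitzky-Golay (SG) smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraSet",
    "RegionTable",
    "SpectraError",
    "load_spectra",
    "save_spectra",
    "snv",
    "msc",
    "sg_smooth",
    "region_proportions",
    "equal_width_regions",
    "RawTransform",
    "SNVTransform",
    "MSCTransform",
    "SGTransform",
    "make_preprocessor",
]


class SpectraError(ValueError):
    """Raised when a spectra table violates its contract."""


@dataclass
class SpectraSet:
    """A wavelength axis, an n x D reflectance matrix, and per-sample labels.

    Wavelengths are strictly increasing; the row count of ``reflectance``
    matches ``labels`` and ``sample_ids``; no value may be missing.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.labels = np.asarray(self.labels)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.wavelengths.ndim != 1:
            raise SpectraError("wavelengths must be a 1-D vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        n, d = self.reflectance.shape
        if d != self.wavelengths.size:
            raise SpectraError(
                f"reflectance has {d} columns but the axis has "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.labels.shape != (n,):
            raise SpectraError(f"expected {n} labels, got {self.labels.shape}")
        if self.sample_ids.shape != (n,):
            raise SpectraError(f"expected {n} sample ids, got {self.sample_ids.shape}")
        if not np.all(np.isfinite(self.reflectance)):
            i, j = np.argwhere(~np.isfinite(self.reflectance))[0]
            raise SpectraError(
                f"non-finite reflectance at sample {self.sample_ids[i]!r}, "
                f"wavelength {self.wavelengths[j]:g}"
            )

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        """A copy of this set with the reflectance matrix replaced."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=np.asarray(reflectance, dtype=float),
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
        )

    def subset_samples(self, idx: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[idx],
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
        )


@dataclass
class RegionTable:
    """Half-open wavelength regions and the share of selected bands in each."""

    boundaries: list = field(default_factory=list)  # (low, high) in nm
    proportions: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "regions": [
                {"low_nm": float(lo), "high_nm": float(hi), "proportion": float(p)}
                for (lo, hi), p in zip(self.boundaries, self.proportions)
            ]
        }


def load_spectra(path, label_column: str = "label", id_column: str | None = None) -> SpectraSet:
    """Read a delimited spectra table into a :class:`SpectraSet`.

    Header columns other than the label/id columns must parse as wavelengths;
    columns are reordered so the axis is ascending.  Missing or non-numeric
    cells and duplicate wavelengths are rejected with a located error.
    """
    import csv

    with open(path, newline="") as fh:
        raw_header = next(csv.reader(fh), [])
    if len(set(raw_header)) != len(raw_header):
        raise SpectraError(f"duplicate column names (wavelengths?) in header of {path}")

    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise SpectraError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].to_numpy()
    drop = [label_column]
    if id_column is not None and id_column in df.columns:
        sample_ids = df[id_column].to_numpy()
        drop.append(id_column)
    else:
        sample_ids = np.arange(len(df))
    spec = df.drop(columns=drop)

    try:
        wavelengths = np.array([float(c) for c in spec.columns])
    except ValueError as exc:
        raise SpectraError(f"non-numeric wavelength header in {path}: {exc}") from exc
    if np.unique(wavelengths).size != wavelengths.size:
        raise SpectraError(f"duplicate wavelengths in header of {path}")

    for col in spec.columns:
        numeric = pd.to_numeric(spec[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SpectraError(
                f"missing or non-numeric reflectance at row {row}, column {col!r}"
            )
        spec[col] = numeric

    order = np.argsort(wavelengths)
    return SpectraSet(
        wavelengths=wavelengths[order],
        reflectance=spec.to_numpy(dtype=float)[:, order],
        labels=labels,
        sample_ids=sample_ids,
    )


def save_spectra(s: SpectraSet, path, label_column: str = "label") -> None:
    """Write a :class:`SpectraSet` in the same CSV dialect ``load_spectra`` reads."""
    df = pd.DataFrame(s.reflectance, columns=[f"{w:.2f}" for w in s.wavelengths])
    df[label_column] = s.labels
    df.insert(0, "sample_id", s.sample_ids)
    df.to_csv(path, index=False)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: z-score each spectrum (mean 0, sample sd 1)."""
    r = s.reflectance
    mean = r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        ids = ", ".join(repr(x) for x in s.sample_ids[flat])
        raise SpectraError(f"constant spectra cannot be SNV-normalised: {ids}")
    return s.with_reflectance((r - mean) / sd)


def msc(
    s: SpectraSet,
    reference: np.ndarray | None = None,
    b_tol: float = 1e-12,
) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed as ``x = a + b * reference`` by ordinary
    least squares and corrected to ``(x - a) / b``.  The reference defaults to
    the column-wise mean spectrum of ``s``; pass the training-set reference
    explicitly to correct held-out data without leakage.
    """
    r = s.reflectance
    ref = r.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (s.n_bands,):
        raise SpectraError(
            f"reference length {ref.size} does not match {s.n_bands} bands"
        )
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise SpectraError("MSC reference has zero variance")
    b = (r - r.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < b_tol)
    if bad.size:
        ids = ", ".join(repr(x) for x in s.sample_ids[bad])
        raise SpectraError(f"MSC slope below tolerance for samples: {ids}")
    a = r.mean(axis=1) - b * ref.mean()
    return s.with_reflectance((r - a[:, None]) / b[:, None])


def sg_smooth(s: SpectraSet, window: int = 11, polyorder: int = 3) -> SpectraSet:
    """Savitzky-Golay smoothing of each spectrum.

    Edge samples are handled by fitting the terminal-window polynomial and
    evaluating it (no shrinkage of the spectrum).
    """
    if window % 2 == 0:
        raise SpectraError(f"SG window must be odd, got {window}")
    if polyorder >= window:
        raise SpectraError(
            f"SG polyorder ({polyorder}) must be smaller than window ({window})"
        )
    if window > s.n_bands:
        raise SpectraError(
            f"SG window ({window}) exceeds the number of bands ({s.n_bands})"
        )
    smoothed = savgol_filter(s.reflectance, window, polyorder, axis=1, mode="interp")
    return s.with_reflectance(smoothed)


def equal_width_regions(wavelengths: np.ndarray, n_regions: int = 6) -> list:
    """Split the axis span into ``n_regions`` equal-width half-open intervals."""
    w = np.asarray(wavelengths, dtype=float)
    edges = np.linspace(w[0], w[-1], n_regions + 1)
    # widen the last edge a hair so the final wavelength falls inside
    edges[-1] = np.nextafter(edges[-1], np.inf)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_regions)]


def region_proportions(selected, wavelengths: np.ndarray, regions: list) -> RegionTable:
    """Fraction of the selected bands falling into each wavelength region.

    ``regions`` is a list of half-open ``[low, high)`` intervals that must
    jointly cover the axis without overlap.  Proportions sum to 1 whenever the
    selection is nonempty; an empty selection is an error.
    """
    w = np.asarray(wavelengths, dtype=float)
    sel = np.asarray(sorted(set(int(i) for i in selected)), dtype=int)
    if sel.size == 0:
        raise SpectraError("cannot compute region proportions of an empty selection")
    if sel.min() < 0 or sel.max() >= w.size:
        raise SpectraError("selected band index out of range")

    membership = np.zeros(w.size, dtype=int)
    for k, (lo, hi) in enumerate(regions):
        if hi <= lo:
            raise SpectraError(f"degenerate region ({lo}, {hi})")
        inside = (w >= lo) & (w < hi)
        membership[inside] += 1
    if np.any(membership == 0):
        j = int(np.argmax(membership == 0))
        raise SpectraError(f"regions do not cover wavelength {w[j]:g}")
    if np.any(membership > 1):
        j = int(np.argmax(membership > 1))
        raise SpectraError(f"regions overlap at wavelength {w[j]:g}")

    counts = np.zeros(len(regions))
    for k, (lo, hi) in enumerate(regions):
        counts[k] = np.count_nonzero((w[sel] >= lo) & (w[sel] < hi))
    return RegionTable(boundaries=list(regions), proportions=counts / sel.size)


# ---------------------------------------------------------------------------
# fit/transform wrappers used by the evaluation harness (train-only statistics)


class RawTransform:
    """Identity preprocessor."""

    name = "raw"

    def fit(self, s: SpectraSet) -> "RawTransform":
        return self

    def transform(self, s: SpectraSet) -> SpectraSet:
        return s


class SNVTransform:
    name = "snv"

    def fit(self, s: SpectraSet) -> "SNVTransform":
        return self  # row-wise, nothing to learn

    def transform(self, s: SpectraSet) -> SpectraSet:
        return snv(s)


class MSCTransform:
    """MSC whose reference is the mean spectrum of the fitted (training) set."""

    name = "msc"

    def __init__(self) -> None:
        self.reference_: np.ndarray | None = None

    def fit(self, s: SpectraSet) -> "MSCTransform":
        self.reference_ = s.reflectance.mean(axis=0)
        return self

    def transform(self, s: SpectraSet) -> SpectraSet:
        if self.reference_ is None:
            raise SpectraError("MSCTransform must be fitted before transform")
        return msc(s, reference=self.reference_)


class SGTransform:
    name = "sg"

    def __init__(self, window: int = 11, polyorder: int = 3) -> None:
        self.window = window
        self.polyorder = polyorder

    def fit(self, s: SpectraSet) -> "SGTransform":
        return self

    def transform(self, s: SpectraSet) -> SpectraSet:
        return sg_smooth(s, self.window, self.polyorder)


_PREPROCESSORS = {
    "raw": RawTransform,
    "none": RawTransform,
    "snv": SNVTransform,
    "msc": MSCTransform,
    "sg": SGTransform,
}


def make_preprocessor(name: str):
    try:
        return _PREPROCESSORS[name.lower()]()
    except KeyError:
        raise SpectraError(
            f"unknown preprocessor {name!r}; choose from {sorted(_PREPROCESSORS)}"
        ) from None
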