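"""Statistics for ToF-SIMS spectra of exposed vs. control cells.

Spectra are reduced to unit-mass bins restricted to 200-1200 u (low masses
carry salts and medium contaminants) and peak-sum normalized to 100% so
that spectra with different total ion doses are comparable.  Group structure
is explored with PCA and tested with a regularized Fisher linear
discriminant under leave-one-out cross-validation; individual lipid ions are
compared between groups as relative intensity (% of the control mean) with a
per-ion Welch test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Spectrum",
    "BinnedSpectrum",
    "SpectrumBinner",
    "preprocess_spectrum",
    "spectra_to_matrix",
    "pca_scores",
    "fisher_lda_loocv",
    "compare_ion_yields",
]

DEFAULT_MASS_RANGE = (200, 1200)


@dataclass(frozen=True)
class Spectrum:
    """Raw spectrum: strictly increasing m/z channels with intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray
    group: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)
        if mz.ndim != 1 or it.shape != mz.shape:
            raise ValueError("mz and intensity must be 1-D and equal length")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(it)) or np.any(it < 0):
            raise ValueError("intensities must be finite and >= 0")


@dataclass(frozen=True)
class BinnedSpectrum:
    """Unit-mass binned, peak-sum-normalized spectrum (intensities sum to 100)."""

    masses: np.ndarray  # integer u
    intensities: np.ndarray  # % of peak sum
    mass_range: tuple[int, int]
    group: str = ""
    replicate_id: str = ""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # ties at .5 round up (np.round would round to even)
    return np.floor(x + 0.5).astype(int)


def preprocess_spectrum(
    spectrum: Spectrum,
    range_low: int = DEFAULT_MASS_RANGE[0],
    range_high: int = DEFAULT_MASS_RANGE[1],
) -> BinnedSpectrum:
    """Unit-mass binning, mass-range restriction and peak-sum normalization.

    Channel intensities are summed into nearest-integer mass bins, bins
    outside ``[range_low, range_high]`` are dropped, and the retained bins
    are rescaled to sum to 100%.  Already binned, normalized input passes
    through unchanged (idempotence).
    """
    bins = _round_half_up(spectrum.mz)
    keep = (bins >= range_low) & (bins <= range_high)
    if not np.any(keep) or float(spectrum.intensity[keep].sum()) == 0.0:
        raise ValueError(f"no signal in the mass range [{range_low}, {range_high}]")
    binned: dict[int, float] = {}
    for b, y in zip(bins[keep], spectrum.intensity[keep]):
        binned[int(b)] = binned.get(int(b), 0.0) + float(y)
    masses = np.array(sorted(binned), dtype=int)
    inten = np.array([binned[m] for m in masses])
    inten = 100.0 * inten / inten.sum()
    return BinnedSpectrum(
        masses=masses,
        intensities=inten,
        mass_range=(range_low, range_high),
        group=spectrum.group,
        replicate_id=spectrum.replicate_id,
    )


class SpectrumBinner(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`preprocess_spectrum` over spectrum lists."""

    def __init__(self, range_low: int = DEFAULT_MASS_RANGE[0], range_high: int = DEFAULT_MASS_RANGE[1]):
        self.range_low = range_low
        self.range_high = range_high

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[BinnedSpectrum]:
        return [preprocess_spectrum(s, self.range_low, self.range_high) for s in X]


def spectra_to_matrix(binned: list[BinnedSpectrum]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack binned spectra on their union mass grid.

    Returns ``(X, masses, groups)`` with X shaped (n_spectra, n_bins);
    missing bins are 0.
    """
    if not binned:
        raise ValueError("no spectra")
    masses = np.array(sorted({int(m) for b in binned for m in b.masses}))
    index = {m: i for i, m in enumerate(masses)}
    X = np.zeros((len(binned), masses.size))
    for r, b in enumerate(binned):
        for m, y in zip(b.masses, b.intensities):
            X[r, index[int(m)]] = y
    groups = np.array([b.group for b in binned])
    return X, masses, groups


def pca_scores(binned: list[BinnedSpectrum], n_components: int | None = None):
    """Centered PCA over the binned spectra.

    Returns ``(scores, explained_variance_ratio, loadings, masses)``.
    """
    X, masses, _ = spectra_to_matrix(binned)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 spectra")
    k = n_components if n_components is not None else min(X.shape[0] - 1, X.shape[1])
    k = max(k, 1)
    pca = PCA(n_components=k)
    # zero total variance (identical spectra) yields 0/0 ratios; report 0
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(X)
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return scores, evr, pca.components_, masses


def fisher_lda_loocv(
    binned: list[BinnedSpectrum],
    shrinkage: float = 0.1,
) -> tuple[LinearDiscriminantAnalysis, float, np.ndarray]:
    """Fisher discriminant with leave-one-out cross-validated accuracy.

    Because the bin count far exceeds the spectra per group (n = 6), the
    within-group scatter is regularized by shrinking toward a scaled
    identity (fixed ``shrinkage``).  Returns the model fitted on all
    spectra, the LOOCV accuracy, and the per-fold predicted labels.
    """
    X, _, groups = spectra_to_matrix(binned)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("need at least 2 spectra per group")

    def make_model() -> LinearDiscriminantAnalysis:
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)

    predicted = np.empty(X.shape[0], dtype=object)
    for train_idx, test_idx in LeaveOneOut().split(X):
        if np.unique(groups[train_idx]).size < 2:
            raise ValueError("a fold lost a whole group; need more spectra")
        m = make_model().fit(X[train_idx], groups[train_idx])
        predicted[test_idx[0]] = m.predict(X[test_idx])[0]
    accuracy = float(np.mean(predicted == groups))
    final = make_model().fit(X, groups)
    return final, accuracy, predicted


def compare_ion_yields(
    binned: list[BinnedSpectrum],
    target_masses: list[int],
    control_group: str,
    alpha: float = 0.05,
    correct_multiple: bool = False,
) -> pd.DataFrame:
    """Per-ion relative intensity of each exposed group vs. the control.

    For every target mass bin and every non-control group, the mean
    normalized intensity is expressed as % of the control-group mean and
    Welch's two-sample t test supplies a significance flag at ``alpha``.
    Bins where the control mean is 0 are reported with missing values.
    An optional Benjamini-Hochberg correction (off by default, matching the
    per-ion convention of reporting uncorrected asterisks) adjusts within
    each group across the target bins.
    """
    X, masses, groups = spectra_to_matrix(binned)
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} not present")
    index = {int(m): i for i, m in enumerate(masses)}
    ctrl = X[groups == control_group]
    if ctrl.shape[0] < 2:
        raise ValueError("need at least 2 control spectra")
    rows = []
    for g in sorted(set(groups) - {control_group}):
        exp = X[groups == g]
        if exp.shape[0] < 2:
            raise ValueError(f"need at least 2 spectra in group {g!r}")
        for m in target_masses:
            i = index.get(int(m))
            if i is None or ctrl[:, i].mean() == 0:
                rows.append(
                    {"group": g, "mass": int(m), "relative_pct": np.nan, "p_value": np.nan,
                     "significant": False, "missing": True}
                )
                continue
            rel = 100.0 * exp[:, i].mean() / ctrl[:, i].mean()
            _, p = stats.ttest_ind(exp[:, i], ctrl[:, i], equal_var=False)
            rows.append(
                {"group": g, "mass": int(m), "relative_pct": float(rel),
                 "p_value": float(p), "significant": bool(p <= alpha), "missing": False}
            )
    out = pd.DataFrame(rows)
    if correct_multiple and len(out):
        out["p_value_adj"] = np.nan
        for _, sub in out.groupby("group"):
            mask = sub["p_value"].notna()
            if mask.any():
                rej, p_adj, *_ = multipletests(
                    sub.loc[mask, "p_value"], alpha=alpha, method="fdr_bh"
                )
                out.loc[sub.index[mask], "p_value_adj"] = p_adj
                out.loc[sub.index[mask], "significant"] = rej
    return out
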