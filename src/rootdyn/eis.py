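"""Electrical impedance spectra and CLAFIC subspace classification.

A spectrum is the complex impedance Z measured at 36 frequencies between
90 Hz and 200 kHz.  Derived quantities: magnitude ``|Z| = sqrt(Re^2 +
Im^2)`` and the loss factor (phase angle) ``delta = arctan(Im/Re)``
(negative = capacitive, positive = inductive).

CLAFIC (class-featuring information compression) classifies a spectrum by
the squared length of its projection onto each class's principal subspace:
per class, the top-``k`` eigenvectors of the *uncentered* second-moment
matrix of unit-norm feature vectors form an orthonormal basis; ``k = 1``
therefore captures approximately the mean spectrum of a class, and larger
``k`` takes the fine structure into account.  Features are unit-norm
(classification is invariant to per-spectrum positive scaling) and
restricted to a 150 Hz – 150 kHz window by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EISpectrum",
    "spectrum_features",
    "ClaficModel",
    "clafic_fit",
    "clafic_classify",
    "clafic_evaluate",
    "spectra_to_frame",
    "spectra_from_frame",
]

DEFAULT_WINDOW = (150.0, 150e3)
FEATURE_KINDS = ("z_re", "z_im", "delta", "magnitude")


@dataclass
class EISpectrum:
    """One impedance spectrum with labels."""

    frequencies_hz: np.ndarray
    z_re: np.ndarray
    z_im: np.ndarray
    sample_id: str = ""
    tissue: str = "root"   # root | stem
    label: str = ""        # treatment class

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.z_re = np.asarray(self.z_re, dtype=float)
        self.z_im = np.asarray(self.z_im, dtype=float)
        if not (self.frequencies_hz.size == self.z_re.size == self.z_im.size):
            raise ValueError("frequency and impedance arrays must align")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.z_re, self.z_im)

    @property
    def loss_factor(self) -> np.ndarray:
        """Phase angle delta = arctan(Z_Im / Z_Re), in radians."""
        return np.arctan2(self.z_im, self.z_re)


def spectrum_features(
    spectrum: EISpectrum,
    feature: str = "z_re",
    window: tuple[float, float] = DEFAULT_WINDOW,
    normalize: bool = True,
) -> np.ndarray:
    """Feature vector: one impedance quantity restricted to ``window``,
    unit-norm scaled (the classical subspace-method convention)."""
    if feature not in FEATURE_KINDS:
        raise ValueError(f"feature must be one of {FEATURE_KINDS}")
    lo, hi = window
    m = (spectrum.frequencies_hz >= lo) & (spectrum.frequencies_hz <= hi)
    if not np.any(m):
        raise ValueError("empty frequency window")
    vec = {
        "z_re": spectrum.z_re,
        "z_im": spectrum.z_im,
        "delta": spectrum.loss_factor,
        "magnitude": spectrum.magnitude,
    }[feature][m]
    if normalize:
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError("zero feature vector cannot be normalized")
        vec = vec / norm
    return vec.astype(float)


@dataclass
class ClaficModel:
    """Per-class orthonormal subspace bases over a common feature space."""

    bases: dict[str, np.ndarray]  # label -> (n_features, k)
    k: int
    feature: str
    window: tuple[float, float]

    def __post_init__(self):
        for label, B in self.bases.items():
            gram = B.T @ B
            if not np.allclose(gram, np.eye(B.shape[1]), atol=1e-10):
                raise ValueError(f"class {label!r}: basis not orthonormal")

    @property
    def labels(self) -> list[str]:
        return list(self.bases)


def clafic_fit(features_by_class: dict[str, np.ndarray], k: int,
               feature: str = "z_re", window: tuple[float, float] = DEFAULT_WINDOW) -> ClaficModel:
    """Fit per-class subspaces of dimension ``k``.

    ``features_by_class`` maps label to an (n_samples, n_features) array of
    unit-norm feature vectors.  The basis is the top-``k`` eigenvectors of
    the class second-moment matrix ``X.T @ X / n`` (uncentered — centering
    would break the ``k = 1 ~ class mean`` property).
    """
    bases = {}
    for label, X in features_by_class.items():
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = X.shape
        if k < 1 or k > min(n, p):
            raise ValueError(f"class {label!r}: k={k} exceeds min(n={n}, p={p})")
        moment = X.T @ X / n
        eigval, eigvec = np.linalg.eigh(moment)
        bases[label] = eigvec[:, ::-1][:, :k]
    return ClaficModel(bases=bases, k=k, feature=feature, window=window)


@dataclass
class ClaficDecision:
    label: str | None              # None when ambiguous
    projections: dict[str, float]  # squared projection length per class
    ambiguous: bool
    tied_labels: list[str]


def clafic_classify(model: ClaficModel, vec: np.ndarray, tie_tol: float = 1e-10) -> ClaficDecision:
    """Assign ``vec`` to the class with the largest squared projection
    length onto its subspace; exact ties are flagged ambiguous and all
    argmax classes reported."""
    vec = np.asarray(vec, dtype=float)
    proj = {label: float(np.sum((B.T @ vec) ** 2)) for label, B in model.bases.items()}
    best = max(proj.values())
    tied = [label for label, v in proj.items() if v >= best - tie_tol]
    if len(tied) > 1:
        return ClaficDecision(None, proj, True, tied)
    return ClaficDecision(tied[0], proj, False, tied)


def _collect(features: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {lab: features[labels == lab] for lab in np.unique(labels)}


def clafic_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    k_range,
    feature: str = "z_re",
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Resubstitution and leave-one-out success fractions per ``k``.

    Returns a tidy DataFrame with columns ``k, mode, success, n_ambiguous``
    plus per-(true, assigned) confusion counts in ``confusion``.
    An ambiguous decision never counts as a success.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    n = len(labels)
    rows = []
    for k in k_range:
        by_class = _collect(features, labels)
        model = clafic_fit(by_class, k, feature, window)
        resub = [clafic_classify(model, features[i]) for i in range(n)]
        loo = []
        for i in range(n):
            keep = np.arange(n) != i
            model_i = clafic_fit(_collect(features[keep], labels[keep]), k, feature, window)
            loo.append(clafic_classify(model_i, features[i]))
        for mode, decisions in (("resubstitution", resub), ("leave-one-out", loo)):
            hits = sum(d.label == lab for d, lab in zip(decisions, labels))
            confusion = pd.crosstab(
                pd.Series(labels, name="true"),
                pd.Series([d.label or "ambiguous" for d in decisions], name="assigned"),
            )
            rows.append(
                {
                    "k": k,
                    "mode": mode,
                    "success": hits / n,
                    "n_ambiguous": sum(d.ambiguous for d in decisions),
                    "confusion": confusion,
                }
            )
    return pd.DataFrame(rows)


# -- CSV layer -------------------------------------------------------------

SPECTRA_COLUMNS = ["sample_id", "tissue", "class", "frequency_hz", "z_re_ohm", "z_im_ohm"]


def spectra_to_frame(spectra: list[EISpectrum]) -> pd.DataFrame:
    rows = []
    for s in spectra:
        for f, re, im in zip(s.frequencies_hz, s.z_re, s.z_im):
            rows.append((s.sample_id, s.tissue, s.label, f, re, im))
    return pd.DataFrame(rows, columns=SPECTRA_COLUMNS)


def spectra_from_frame(df: pd.DataFrame) -> list[EISpectrum]:
    out = []
    for (sid, tissue, label), sub in df.groupby(["sample_id", "tissue", "class"], sort=False):
        sub = sub.sort_values("frequency_hz")
        out.append(
            EISpectrum(
                frequencies_hz=sub["frequency_hz"].to_numpy(),
                z_re=sub["z_re_ohm"].to_numpy(),
                z_im=sub["z_im_ohm"].to_numpy(),
                sample_id=sid,
                tissue=tissue,
                label=label,
            )
        )
    return out
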