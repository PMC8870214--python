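"""Unsupervised ordination and reclassification of samples.

Assembles one of three feature sets (all 13 markers' percent + MFI plus
abnormal-cell percentages; the 4 score markers plus genotype; or the
latter extended with blood counts, the CD4/CD8 ratio and CD26), fits a
standardised PCA, draws per-group 90% concentration ellipses in the
PC1-PC2 plane, flags gray-zone samples, and assigns each sample to HCL or
HCL-like by the smaller Mahalanobis distance to the two reference-group
Gaussians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .cohort import PatientRecord, SampleRecord
from .flow import SampleProfile
from .markers import CHCL, GENES, MARKERS_13, VHCL_SDRPL

VARIANTS = ("markers13", "markers4_geno", "markers4_geno_blood")
_SCORE_MARKERS_ORDERED = ("CD11c", "CD103", "CD123", "CD25")
_BLOOD_ANALYTES = ("ALC", "AMC", "ANC", "PC", "Hb")


@dataclass
class FeatureMatrix:
    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # samples x features, imputed
    variant: str
    missing_mask: np.ndarray  # True where the raw value was missing


@dataclass
class PCAModel:
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # features x components, columns orthonormal
    scores: np.ndarray  # samples x components
    explained_pct: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]


@dataclass
class Ellipse:
    group: str
    center: np.ndarray  # PC1-PC2
    covariance: np.ndarray  # 2x2 SPD
    level: float = 0.90

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric 2x2")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        self.covariance = cov

    @property
    def radius_sq(self) -> float:
        """Squared Mahalanobis boundary radius: chi-square quantile, 2 df."""
        return float(stats.chi2.ppf(self.level, df=2))

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.covariance), d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.radius_sq


@dataclass
class ReclassificationResult:
    sample_id: str
    original_group: str
    new_label: str  # HCL | HCL_like | ambiguous
    distances: dict[str, float] = field(default_factory=dict)
    gray_zone: bool = False


# ---------------------------------------------------------------------------
# feature assembly


def _marker_pair(profile: SampleProfile, marker: str) -> tuple[float, float]:
    s = profile.summaries.get(marker)
    if s is None:
        return np.nan, np.nan
    return s.percent_positive, s.mfi


def assemble_features(
    patients: Iterable[PatientRecord],
    samples: Iterable[SampleRecord],
    profiles: Mapping[str, SampleProfile],
    variant: str,
    device_filter: str | None = None,
) -> FeatureMatrix:
    """Build the feature matrix for one ordination variant.

    ``profiles`` maps sample_id to :class:`SampleProfile`.  Missing values
    (markers absent from a panel, untested genotypes, undefined ratios)
    are imputed with the feature's overall mean and flagged in
    ``missing_mask``; untested genotypes are encoded as wild type (0) with
    the mask set, mutated as 1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown feature variant {variant!r}")
    by_pid = {p.patient_id: p for p in patients}
    rows: list[list[float]] = []
    untested_geno: list[list[bool]] = []
    sample_ids: list[str] = []
    if variant == "markers13":
        names = [f"{m}_{k}" for m in MARKERS_13 for k in ("pct", "mfi")]
        names += ["abnormal_pct_of_sample", "abnormal_pct_of_lymphocytes"]
    else:
        names = [f"{m}_{k}" for m in _SCORE_MARKERS_ORDERED for k in ("pct", "mfi")]
        names += ["abnormal_pct_of_sample"]
        if variant == "markers4_geno_blood":
            names += list(_BLOOD_ANALYTES) + ["cd4_cd8_ratio", "CD26_pct", "CD26_mfi"]
        names += ["BRAF_V600E", "MAP2K1", "KLF2"]
    for s in samples:
        if device_filter is not None and s.device != device_filter:
            continue
        if s.sample_id not in profiles:
            continue
        prof = profiles[s.sample_id]
        patient = by_pid[s.patient_id]
        row: list[float] = []
        if variant == "markers13":
            for m in MARKERS_13:
                row.extend(_marker_pair(prof, m))
            row.append(prof.pct_abnormal_of_all_events)
            row.append(prof.infiltration_pct)
        else:
            for m in _SCORE_MARKERS_ORDERED:
                row.extend(_marker_pair(prof, m))
            row.append(prof.pct_abnormal_of_all_events)
            if variant == "markers4_geno_blood":
                row.extend(
                    patient.blood_counts.get(a, np.nan) for a in _BLOOD_ANALYTES
                )
                row.append(
                    np.nan if patient.cd4_cd8_ratio is None else patient.cd4_cd8_ratio
                )
                row.extend(_marker_pair(prof, "CD26"))
            statuses = [patient.genotype.get(g, "untested") for g in GENES]
            # untested encoded as wild type (0) but flagged in the mask
            row.extend(1.0 if s_ == "mutated" else 0.0 for s_ in statuses)
            untested_geno.append([s_ == "untested" for s_ in statuses])
        rows.append(row)
        sample_ids.append(s.sample_id)
    values = np.asarray(rows, dtype=float)
    missing = np.isnan(values)
    if values.size:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            col_means = np.nan_to_num(np.nanmean(values, axis=0))
        values = np.where(missing, col_means, values)
        if variant != "markers13" and untested_geno:
            missing[:, -len(GENES):] |= np.asarray(untested_geno)
    return FeatureMatrix(sample_ids, names, values, variant, missing)


# ---------------------------------------------------------------------------
# PCA


def fit_pca(X: FeatureMatrix | np.ndarray, n_components: int | None = None) -> PCAModel:
    """Standardised PCA (centred, unit-variance features).

    Zero-variance features are dropped with a warning.  Components are
    ordered by decreasing explained variance; each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    if isinstance(X, FeatureMatrix):
        values, names, sample_ids = X.values, list(X.feature_names), X.sample_ids
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(values.shape[1])]
        sample_ids = [str(i) for i in range(values.shape[0])]
    if values.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    center = values.mean(axis=0)
    scale = values.std(axis=0)  # population sd, matching the scaled-PCA default
    keep = scale > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        values = values[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        center, scale = center[keep], scale[keep]
    if values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 features with nonzero variance")
    Z = (values - center) / scale
    max_rank = min(Z.shape[0], Z.shape[1])
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # features x components
    # sign convention: largest-magnitude loading positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    explained = 100.0 * pca.explained_variance_ratio_
    if n_components is not None:
        loadings = loadings[:, :n_components]
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    return PCAModel(center, scale, loadings, scores, explained, names, sample_ids)


# ---------------------------------------------------------------------------
# ellipses, gray zone, reclassification


def concentration_ellipse(
    scores: np.ndarray, group: str = "", level: float = 0.90
) -> Ellipse:
    """Normal-theory concentration ellipse of one group's PC1-PC2 scores.

    A point lies inside iff its squared Mahalanobis distance to the group
    mean is at most the chi-square quantile at ``level`` with 2 df.
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    if pts.shape[0] < 3:
        raise ValueError("concentration ellipse requires >= 3 samples")
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= 0:
        raise ValueError(f"singular covariance for group {group!r}")
    return Ellipse(group, pts.mean(axis=0), cov, level)


def flag_gray_zone(
    scores: np.ndarray,
    labels: Sequence[str],
    ellipses: Mapping[str, Ellipse],
) -> np.ndarray:
    """Per-sample gray-zone flags.

    A sample is gray-zone iff it lies inside the 90% ellipse of a group
    other than its own label, or outside every ellipse.
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    inside = {g: e.contains(pts) for g, e in ellipses.items()}
    flags = np.zeros(pts.shape[0], dtype=bool)
    for i, label in enumerate(labels):
        in_any = any(inside[g][i] for g in ellipses)
        in_other = any(inside[g][i] for g in ellipses if g != label)
        flags[i] = in_other or not in_any
    return flags


def reclassify(
    scores: np.ndarray,
    sample_ids: Sequence[str],
    labels: Sequence[str],
    reference_groups: tuple[str, str] = (CHCL, VHCL_SDRPL),
    level: float = 0.90,
    rel_tol: float = 1e-9,
) -> list[ReclassificationResult]:
    """Nearest-Gaussian assignment of every sample to HCL vs HCL-like.

    Reference Gaussians (mean + covariance in PC1-PC2) are fitted on the
    two reference groups; each sample takes the label of the closer one by
    Mahalanobis distance (first group -> "HCL", second -> "HCL_like").
    Distances equal within relative tolerance give "ambiguous".  Gray-zone
    flags come from the reference groups' 90% ellipses.
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    labels = list(labels)
    ellipses: dict[str, Ellipse] = {}
    for g in reference_groups:
        member = pts[[i for i, lab in enumerate(labels) if lab == g]]
        if member.shape[0] < 3:
            raise ValueError(f"reference group {g!r} has fewer than 3 samples")
        ellipses[g] = concentration_ellipse(member, g, level)
    gray = flag_gray_zone(pts, labels, ellipses)
    target = {reference_groups[0]: "HCL", reference_groups[1]: "HCL_like"}
    out = []
    for i, sid in enumerate(sample_ids):
        dists = {
            g: float(np.sqrt(ellipses[g].mahalanobis_sq(pts[i]))[0])
            for g in reference_groups
        }
        da, db = (dists[g] for g in reference_groups)
        if abs(da - db) <= rel_tol * max(da, db, 1.0):
            label = "ambiguous"
        else:
            label = target[min(dists, key=dists.get)]
        out.append(
            ReclassificationResult(sid, labels[i], label, dists, bool(gray[i]))
        )
    return out


__all__ = [
    "Ellipse",
    "FeatureMatrix",
    "PCAModel",
    "ReclassificationResult",
    "VARIANTS",
    "assemble_features",
    "concentration_ellipse",
    "fit_pca",
    "flag_gray_zone",
    "reclassify",
]
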