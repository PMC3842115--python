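"""PCA of the common-protein matrix: proteins are observations, samples are
variables.

With this orientation each protein receives a *score* (its coordinate on a
component) and each sample a *loading* (its weight in defining the
component).  Columns are mean-centered after the chosen transform (log2 by
default); no variance scaling is applied, so the per-component variance
fractions decompose the total sample variance.  The number of components is
``min(n_proteins - 1, n_samples)``, which captures every nonzero direction
of the column-centered matrix.

Component signs from an eigendecomposition are arbitrary.  A deterministic
convention (largest-magnitude loading positive) makes results bit-stable,
and :func:`orient_components` re-anchors chosen components to sample groups
so that, e.g., hepatic maturity points in the positive PC1 direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidDataError
from .quantio import ExpressionMatrix

logger = logging.getLogger(__name__)

TRANSFORMS = ("log2", "none")


@dataclass
class PCAResult:
    protein_scores: pd.DataFrame    # proteins x components
    sample_loadings: pd.DataFrame   # samples x components (orthonormal columns)
    variance_fraction: pd.Series    # per-component fraction of total variance
    centering: pd.Series            # per-sample mean removed (post-transform)
    transform: str

    @property
    def components(self) -> list[str]:
        return list(self.protein_scores.columns)


def run_pca(m: ExpressionMatrix, transform: str = "log2") -> PCAResult:
    """Full (deterministic, SVD-based) principal component analysis.

    Requires a complete matrix with at least 2 proteins and 2 samples.  A
    constant sample column is retained (it simply contributes nothing after
    centering); an all-constant matrix is a degenerate input.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    if not m.is_complete:
        raise InvalidDataError("PCA requires a complete matrix")
    n_prot, n_samp = m.values.shape
    if n_prot < 2 or n_samp < 2:
        raise InvalidDataError("PCA requires >= 2 proteins and >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    if transform == "log2":
        x = np.log2(x)
    centering = x.mean(axis=0)
    xc = x - centering
    total_var = float((xc ** 2).sum())
    if total_var == 0.0:
        raise DegenerateInputError("all-constant matrix has no principal components")
    n_comp = min(n_prot - 1, n_samp)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    # deterministic sign: the largest-|weight| loading of each component is positive
    for j in range(n_comp):
        pivot = int(np.argmax(np.abs(vt[j])))
        if vt[j, pivot] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    comps = [f"PC{j + 1}" for j in range(n_comp)]
    scores = pd.DataFrame(u * s, index=m.accessions, columns=comps)
    loadings = pd.DataFrame(vt.T, index=m.sample_ids, columns=comps)
    frac = pd.Series(s ** 2 / total_var, index=comps)
    return PCAResult(scores, loadings, frac,
                     pd.Series(centering, index=m.sample_ids), transform)


def orient_components(
    r: PCAResult,
    anchors: Sequence[tuple[str, str, str]],
    meta: pd.DataFrame,
) -> PCAResult:
    """Fix component signs against sample groups.

    Each anchor is ``(component, group, desired_sign)`` with sign in
    ``{"positive", "negative"}``: the component's loadings and scores are
    negated if needed so the anchor group's mean loading carries the desired
    sign.  Variance fractions are unchanged.  An exactly-zero group mean
    leaves the component as computed, with a warning.
    """
    loadings = r.sample_loadings.copy()
    scores = r.protein_scores.copy()
    sample_group = meta.set_index("sample_id")["group"]
    for component, group, desired in anchors:
        if component not in loadings.columns:
            raise ValueError(f"unknown component {component!r}")
        if desired not in ("positive", "negative"):
            raise ValueError(f"anchor sign must be 'positive' or 'negative', got {desired!r}")
        members = sample_group.index[sample_group == group]
        members = [s for s in members if s in loadings.index]
        if not members:
            raise ValueError(f"anchor group {group!r} has no samples in the PCA")
        mean_loading = float(loadings.loc[members, component].mean())
        if mean_loading == 0.0:
            logger.warning("orientation of %s unresolved: %s mean loading is 0",
                           component, group)
            continue
        want_positive = desired == "positive"
        if (mean_loading > 0) != want_positive:
            loadings[component] = -loadings[component]
            scores[component] = -scores[component]
    return replace(r, protein_scores=scores, sample_loadings=loadings)


def write_pca(r: PCAResult, scores_path, loadings_path, variance_path) -> None:
    """Write scores, loadings and variance fractions as three TSV files."""
    s = r.protein_scores.copy()
    s.insert(0, "accession", s.index)
    s.to_csv(scores_path, sep="\t", index=False)
    l = r.sample_loadings.copy()
    l.insert(0, "sample_id", l.index)
    l.to_csv(loadings_path, sep="\t", index=False)
    v = r.variance_fraction.rename("variance_fraction").rename_axis("component")
    v.to_frame().to_csv(variance_path, sep="\t")
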