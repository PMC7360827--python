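"""Correlation-matrix principal component analysis with contribution rates.

The analysis eigendecomposes the trait correlation matrix (sample,
n-1 normalization). With p traits the eigenvalues sum to p, so the
contribution rate of component j is lambda_j / p x 100 and the
accumulative contribution rate is its running sum. Accession scores are
the z-scored data projected on the eigenvectors. Qualitative traits
enter numerically through their integer state codes, exactly as they do
in the clustering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import StandardizedMatrix


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, length p
    loadings: np.ndarray  # p traits x p components, unit-norm columns
    contribution: np.ndarray  # per-component %, lambda_j / p * 100
    cumulative: np.ndarray  # running sum of contribution, ends at 100
    scores: np.ndarray  # n accessions x p components
    trait_codes: list[str]
    accession_ids: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def eigen_report(self, n_components: int | None = None) -> list[dict]:
        """Rows of the eigenvalue/contribution table, one per component."""
        m = n_components or self.n_components
        return [
            {"component": j + 1,
             "eigenvalue": float(self.eigenvalues[j]),
             "contribution_pct": float(self.contribution[j]),
             "cumulative_pct": float(self.cumulative[j])}
            for j in range(m)
        ]

    def to_csv(self, path: str | Path, n_components: int | None = None) -> Path:
        """Eigen-report CSV: eigenvalue, contribution and cumulative rows,
        then the loading of every trait on each retained component."""
        m = n_components or self.n_components
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["row"] + [f"PC{j + 1}" for j in range(m)])
            w.writerow(["eigenvalue"] + [repr(float(v)) for v in self.eigenvalues[:m]])
            w.writerow(["contribution_pct"] + [repr(float(v)) for v in self.contribution[:m]])
            w.writerow(["cumulative_pct"] + [repr(float(v)) for v in self.cumulative[:m]])
            for i, code in enumerate(self.trait_codes):
                w.writerow([code] + [repr(float(v)) for v in self.loadings[i, :m]])
        return path

    def scores_to_csv(self, path: str | Path, n_components: int | None = None) -> Path:
        m = n_components or self.n_components
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id"] + [f"PC{j + 1}" for j in range(m)])
            for i, acc in enumerate(self.accession_ids):
                w.writerow([acc] + [repr(float(v)) for v in self.scores[i, :m]])
        return path


def contribution_rates(eigenvalues, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Contribution % (lambda_j / p x 100) and its cumulative running sum."""
    if p <= 0:
        raise ValueError("p must be positive")
    lam = np.asarray(list(eigenvalues), dtype=float)
    if len(lam) > p:
        raise ValueError("more eigenvalues than traits")
    if (lam < -1e-12).any():
        raise ValueError("eigenvalues must be non-negative")
    contribution = lam / p * 100.0
    return contribution, np.cumsum(contribution)


def correlation_pca(matrix: StandardizedMatrix) -> PCAResult:
    """PCA of the trait correlation matrix of a standardized collection.

    Loading signs are fixed deterministically: each column is flipped so
    that its largest-magnitude entry is positive.
    """
    z = matrix.values
    n, p = z.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 accessions and 2 traits")
    if matrix.constant_traits:
        raise ValueError(
            "correlation undefined for constant trait(s): "
            f"{matrix.constant_traits}")
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading of each column positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    contribution, cumulative = contribution_rates(eigvals, p)
    # score against the correlation estimator's own scaling (sample sd)
    scores = z @ eigvecs
    return PCAResult(
        eigenvalues=eigvals,
        loadings=eigvecs,
        contribution=contribution,
        cumulative=cumulative,
        scores=scores,
        trait_codes=list(matrix.trait_codes),
        accession_ids=list(matrix.accession_ids),
    )


def score_scatter(result: PCAResult, components: tuple[int, int] = (1, 2),
                  labels: dict[str, str] | None = None) -> list[dict]:
    """Per-accession (x, y) score table for a 2-D ordination plot.

    Components are 1-based. An optional accession -> group label map is
    carried through for coloring.
    """
    cx, cy = components
    for c in (cx, cy):
        if not 1 <= c <= result.n_components:
            raise IndexError(f"component {c} out of range 1..{result.n_components}")
    rows = []
    for i, acc in enumerate(result.accession_ids):
        row = {"id": acc,
               "x": float(result.scores[i, cx - 1]),
               "y": float(result.scores[i, cy - 1])}
        if labels is not None:
            row["group"] = labels.get(acc)
        rows.append(row)
    return rows
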