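"""Log-ratio transforms between the simplex and Euclidean space.

Compositional vectors (strictly positive parts with a fixed total, here
kappa = 1) carry only relative information and live on a simplex rather
than in Euclidean space.  The additive (ALR), centred (CLR) and isometric
(ILR) log-ratio transforms map them to real coordinates where Gaussian
models and Euclidean distances are meaningful.  The clustering workflow
uses ALR with the reference time point T0 so that each coordinate reads
as a log fold change relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogRatioTensor",
    "alr",
    "alr_inverse",
    "clr",
    "ilr",
    "pivot_basis",
    "zero_replace",
    "profiles_to_logratio",
    "logratio_to_profiles",
    "logratio_to_tsv",
]

# Parts below this floor are rejected rather than silently clamped.
_POSITIVE_FLOOR = 1e-300


@dataclass
class LogRatioTensor:
    """ALR coordinates of normalised expression profiles.

    ``data`` has shape (n_genes, J, T-1): per gene, a J x (T-1) matrix with
    experiments as rows and non-reference time points (chronological) as
    columns.
    """

    data: np.ndarray
    gene_ids: list[str]
    experiment_labels: list[str]
    time_labels: list[str]  # labels of the T-1 non-reference time points
    ref_time: str = "T0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("LogRatioTensor data must be 3-dimensional (gene, experiment, time)")
        n, j, t = self.data.shape
        if len(self.gene_ids) != n or len(self.experiment_labels) != j or len(self.time_labels) != t:
            raise ValueError("LogRatioTensor labels do not match data shape")

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.data.shape[1]

    @property
    def n_timecols(self) -> int:
        return self.data.shape[2]

    def flattened(self) -> np.ndarray:
        """Genes x (J*(T-1)) matrix for two-way (flattened) clustering."""
        return self.data.reshape(self.n_genes, -1)


def _check_positive(x: np.ndarray, op: str) -> None:
    if np.any(x < _POSITIVE_FLOOR):
        raise ValueError(
            f"{op} requires strictly positive parts (floor {_POSITIVE_FLOOR:g}); "
            "apply zero_replace or a pseudo-count first"
        )


def alr(x: np.ndarray, ref: int = 0) -> np.ndarray:
    """Additive log-ratio transform: ln(x_d / x_ref) for d != ref.

    Coordinates keep the original part order with the reference removed.
    Operates on the last axis; accepts a single composition or a stack.
    """
    x = np.asarray(x, dtype=float)
    _check_positive(x, "alr")
    d = x.shape[-1]
    ref = int(ref) % d
    logx = np.log(x)
    out = logx - logx[..., ref : ref + 1]
    return np.delete(out, ref, axis=-1)


def alr_inverse(z: np.ndarray, ref: int = 0, total: float = 1.0) -> np.ndarray:
    """Map ALR coordinates back to the simplex (closure of exp).

    A zero is inserted at the reference position before exponentiation;
    max-subtraction keeps the computation stable for large coordinates.
    """
    z = np.asarray(z, dtype=float)
    full = np.insert(z, min(int(ref), z.shape[-1]), 0.0, axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return total * e / e.sum(axis=-1, keepdims=True)


def clr(x: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform: ln(x_d / g(x)) with g the geometric mean."""
    x = np.asarray(x, dtype=float)
    _check_positive(x, "clr")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def pivot_basis(d: int) -> np.ndarray:
    """Orthonormal pivot-coordinate contrast matrix, shape (d-1, d).

    Row l (1-based) is sqrt((d-l)/(d-l+1)) * (0,...,0, 1, -1/(d-l), ...,
    -1/(d-l)); ILR(x) = CLR(x) @ basis.T.
    """
    if d < 2:
        raise ValueError("pivot basis needs at least 2 parts")
    basis = np.zeros((d - 1, d))
    for l in range(d - 1):
        r = d - l - 1  # number of trailing parts balanced against part l
        basis[l, l] = np.sqrt(r / (r + 1.0))
        basis[l, l + 1 :] = -np.sqrt(r / (r + 1.0)) / r
    return basis


def ilr(x: np.ndarray) -> np.ndarray:
    """Isometric log-ratio transform with the pivot-coordinate basis.

    ILR is an isometry: Euclidean distances between ILR images equal the
    Aitchison distances (equivalently the distances of the CLR images).
    """
    x = np.asarray(x, dtype=float)
    _check_positive(x, "ilr")
    return clr(x) @ pivot_basis(x.shape[-1]).T


def zero_replace(x: np.ndarray, c: float, total: float = 1.0) -> np.ndarray:
    """Additive pseudo-count: add c to every part, re-close to ``total``."""
    x = np.asarray(x, dtype=float)
    if c <= 0:
        raise ValueError("pseudo-count c must be positive")
    if np.any(x < 0):
        raise ValueError("parts must be non-negative")
    shifted = x + c
    return total * shifted / shifted.sum(axis=-1, keepdims=True)


def profiles_to_logratio(profiles, ref_time: int | str = 0) -> LogRatioTensor:
    """ALR-transform a ProfileTensor along the time axis, per gene and experiment.

    Produces per gene a J x (T-1) matrix with experiments as rows and the
    non-reference time points, in chronological order, as columns.
    """
    p = np.asarray(profiles.profiles, dtype=float)  # (n, T, J)
    if np.any(p <= 0):
        raise ValueError(
            "profiles contain non-positive entries; use a positive pseudo-count "
            "(c > 0) or zero_replace before the log-ratio transform"
        )
    labels = list(profiles.time_labels)
    ref_idx = labels.index(ref_time) if isinstance(ref_time, str) else int(ref_time)
    coords = alr(np.transpose(p, (0, 2, 1)), ref=ref_idx)  # (n, J, T-1)
    kept = [lab for i, lab in enumerate(labels) if i != ref_idx]
    return LogRatioTensor(
        data=coords,
        gene_ids=list(profiles.gene_ids),
        experiment_labels=list(profiles.experiment_labels),
        time_labels=kept,
        ref_time=labels[ref_idx],
    )


def logratio_to_profiles(tensor: LogRatioTensor, ref_position: int = 0) -> np.ndarray:
    """Invert profiles_to_logratio; returns an (n, T, J) profile array."""
    comps = alr_inverse(tensor.data, ref=ref_position)  # (n, J, T)
    return np.transpose(comps, (0, 2, 1))


def logratio_to_tsv(tensor: LogRatioTensor, path) -> None:
    """Write long-format TSV (gene, experiment, time, coordinate)."""
    import pandas as pd

    n, j, t = tensor.data.shape
    rows = pd.DataFrame(
        {
            "gene": np.repeat(tensor.gene_ids, j * t),
            "experiment": np.tile(np.repeat(tensor.experiment_labels, t), n),
            "time": np.tile(tensor.time_labels, n * j),
            "coordinate": tensor.data.ravel(),
        }
    )
    rows.to_csv(path, sep="\t", index=False)
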