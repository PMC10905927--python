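"""Raw counts -> normalised expression profiles.

For gene i, time point t and experiment j the normalised expression profile

    p_itj = (x_itj / s_tj + c) / (sum_t x_itj / s_tj + c * T)

gives the proportion of depth-corrected reads for the gene in that
experiment across the T time points; per gene and experiment the T values
are strictly positive (for c > 0) and sum to one, so each profile is a
composition.  Size factors s are median-of-ratios estimates, one per
sample, normalised to geometric mean one.  Profiles are computed per
replicate and then averaged over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTensor",
    "SizeFactors",
    "ProfileTensor",
    "read_count_table",
    "estimate_size_factors",
    "normalized_profiles",
    "average_replicates",
    "filter_genes",
    "profiles_to_tsv",
]


@dataclass
class CountTensor:
    """Raw read counts indexed (gene, time, experiment, replicate).

    ``counts`` has shape (n, T, J, R); ``time_labels`` are ordered with the
    reference time point T0 first.
    """

    counts: np.ndarray
    gene_ids: list[str]
    time_labels: list[str]
    experiment_labels: list[str]
    replicate_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-dimensional (gene, time, experiment, replicate)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.equal(np.mod(self.counts, 1), 0)):
            raise ValueError("counts must be integral")
        n, t, j, r = self.counts.shape
        if (len(self.gene_ids), len(self.time_labels), len(self.experiment_labels),
                len(self.replicate_labels)) != (n, t, j, r):
            raise ValueError("label lengths do not match counts shape")

    def as_sample_matrix(self) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
        """Flatten to genes x samples; returns (matrix, list of (t, j, r) per column)."""
        n, t, j, r = self.counts.shape
        keys = [(tt, jj, rr) for tt in range(t) for jj in range(j) for rr in range(r)]
        mat = self.counts.reshape(n, t * j * r)
        return mat, keys


@dataclass
class SizeFactors:
    """Per-sample scaling factors s_{tjr}, geometric mean 1 across samples."""

    s: np.ndarray  # shape (T, J, R)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0):
            raise ValueError("size factors must be strictly positive")


@dataclass
class ProfileTensor:
    """Normalised expression profiles p_itj, shape (n, T, J); unit sum over t."""

    profiles: np.ndarray
    gene_ids: list[str]
    time_labels: list[str]
    experiment_labels: list[str]
    pseudo_constant: float = 1.0

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 3:
            raise ValueError("profiles must be 3-dimensional (gene, time, experiment)")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("profiles must sum to 1 over time for every gene and experiment")


def read_count_table(counts_path, metadata_path) -> CountTensor:
    """Read a delimited count matrix plus sample metadata into a CountTensor.

    The count table's first column holds gene identifiers; the metadata table
    needs columns sample, experiment, time, replicate.  Time values are
    sorted; the smallest becomes the reference T0.
    """
    counts = pd.read_csv(counts_path, sep=None, engine="python", index_col=0)
    meta = pd.read_csv(metadata_path, sep=None, engine="python")
    required = {"sample", "experiment", "time", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required column(s): {sorted(missing)}")
    missing_samples = [s for s in meta["sample"] if s not in counts.columns]
    if missing_samples:
        raise ValueError(f"metadata samples absent from count table: {missing_samples}")

    time_labels = sorted(meta["time"].unique())
    experiment_labels = sorted(map(str, meta["experiment"].astype(str).unique()))
    replicate_labels = sorted(map(str, meta["replicate"].astype(str).unique()))
    n = counts.shape[0]
    shape = (n, len(time_labels), len(experiment_labels), len(replicate_labels))
    arr = np.full(shape, -1, dtype=np.int64)
    for _, row in meta.iterrows():
        ti = time_labels.index(row["time"])
        ji = experiment_labels.index(str(row["experiment"]))
        ri = replicate_labels.index(str(row["replicate"]))
        if arr[0, ti, ji, ri] != -1:
            raise ValueError(f"duplicate sample for (time={row['time']}, experiment="
                             f"{row['experiment']}, replicate={row['replicate']})")
        arr[:, ti, ji, ri] = counts[row["sample"]].to_numpy()
    if np.any(arr < 0):
        raise ValueError("metadata does not cover every (time, experiment, replicate) cell")
    return CountTensor(
        counts=arr,
        gene_ids=list(map(str, counts.index)),
        time_labels=[str(t) for t in time_labels],
        experiment_labels=experiment_labels,
        replicate_labels=replicate_labels,
    )


def estimate_size_factors(counts_by_sample: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors for a genes x samples count matrix.

    For each sample, the factor is the median over reference genes (genes
    with strictly positive counts in all samples) of that sample's count
    divided by the gene's across-sample geometric mean; factors are then
    rescaled to geometric mean one.
    """
    x = np.asarray(counts_by_sample, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a genes x samples matrix")
    if np.any(x.sum(axis=0) == 0):
        raise ValueError("at least one sample has all-zero counts")
    all_positive = np.all(x > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "size factors via median-of-ratios are undefined"
        )
    ref = x[all_positive]
    geo = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
    factors = np.median(ref / geo, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalized_profiles(counts: CountTensor, size_factors: SizeFactors | None = None,
                        c: float = 1.0) -> list[ProfileTensor]:
    """Per-replicate normalised expression profiles.

    Returns one ProfileTensor per replicate, sharing gene/time/experiment
    labels; size factors are estimated per sample (median-of-ratios) when
    not supplied.
    """
    if c < 0:
        raise ValueError("pseudo-constant c must be non-negative")
    x = counts.counts.astype(float)  # (n, T, J, R)
    n, t, j, r = x.shape
    if size_factors is None:
        mat, _ = counts.as_sample_matrix()
        s = estimate_size_factors(mat).reshape(t, j, r)
        size_factors = SizeFactors(s=s)
    scaled = x / size_factors.s[None, :, :, :]
    denom = scaled.sum(axis=1, keepdims=True) + c * t
    if np.any(denom == 0):
        bad = np.argwhere(denom[:, 0] == 0)
        g, jj, rr = bad[0]
        raise ValueError(
            f"zero profile denominator for gene {counts.gene_ids[g]!r}, experiment "
            f"{counts.experiment_labels[jj]!r}, replicate {counts.replicate_labels[rr]!r} "
            "(all counts zero and c = 0)"
        )
    p = (scaled + c) / denom  # (n, T, J, R)
    return [
        ProfileTensor(
            profiles=p[:, :, :, rep],
            gene_ids=counts.gene_ids,
            time_labels=counts.time_labels,
            experiment_labels=counts.experiment_labels,
            pseudo_constant=c,
        )
        for rep in range(r)
    ]


def half_min_positive_pseudocount(counts: CountTensor) -> float:
    """Alternative pseudo-constant: half the minimum positive raw count."""
    positive = counts.counts[counts.counts > 0]
    if positive.size == 0:
        raise ValueError("all counts are zero; no positive minimum exists")
    return float(positive.min()) / 2.0


def average_replicates(profiles_per_replicate: list[ProfileTensor]) -> ProfileTensor:
    """Entrywise arithmetic mean over replicates (means of unit-sum vectors)."""
    if not profiles_per_replicate:
        raise ValueError("no replicate profiles given")
    first = profiles_per_replicate[0]
    stacks = []
    for pt in profiles_per_replicate:
        if pt.profiles.shape != first.profiles.shape:
            raise ValueError("replicate profile tensors have mismatched shapes")
        stacks.append(pt.profiles)
    mean = np.mean(stacks, axis=0)
    return ProfileTensor(
        profiles=mean,
        gene_ids=first.gene_ids,
        time_labels=first.time_labels,
        experiment_labels=first.experiment_labels,
        pseudo_constant=first.pseudo_constant,
    )


def filter_genes(profiles: ProfileTensor, keep) -> ProfileTensor:
    """Subset to a gene-id set, e.g. externally determined DE genes.

    The original gene order is preserved; identifiers not present in the
    tensor are reported via a warning attribute on the return path.
    """
    keep = set(keep)
    unknown = keep - set(profiles.gene_ids)
    mask = [g in keep for g in profiles.gene_ids]
    if not any(mask):
        raise ValueError("gene filter leaves no genes (empty intersection with gene_ids)")
    if unknown:
        import warnings

        warnings.warn(f"{len(unknown)} filter id(s) not present in the profile tensor",
                      stacklevel=2)
    idx = np.flatnonzero(mask)
    return ProfileTensor(
        profiles=profiles.profiles[idx],
        gene_ids=[profiles.gene_ids[i] for i in idx],
        time_labels=profiles.time_labels,
        experiment_labels=profiles.experiment_labels,
        pseudo_constant=profiles.pseudo_constant,
    )


def profiles_to_tsv(profiles: ProfileTensor, path) -> None:
    """Write long-format TSV (gene, experiment, time, value)."""
    n, t, j = profiles.profiles.shape
    df = pd.DataFrame(
        {
            "gene": np.repeat(profiles.gene_ids, t * j),
            "experiment": np.tile(np.tile(profiles.experiment_labels, t), n),
            "time": np.tile(np.repeat(profiles.time_labels, j), n),
            "value": profiles.profiles.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def profiles_from_tsv(path) -> ProfileTensor:
    """Read the long-format profile TSV written by profiles_to_tsv."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "experiment": str, "time": str})
    gene_ids = list(dict.fromkeys(df["gene"]))
    time_labels = sorted(df["time"].unique())
    experiment_labels = sorted(df["experiment"].unique())
    arr = (
        df.set_index(["gene", "time", "experiment"])["value"]
        .unstack(["time", "experiment"])  # columns ordered below
        .reindex(gene_ids)
    )
    n = len(gene_ids)
    out = np.empty((n, len(time_labels), len(experiment_labels)))
    for ti, t in enumerate(time_labels):
        for ji, j in enumerate(experiment_labels):
            out[:, ti, ji] = arr[(t, j)].to_numpy()
    return ProfileTensor(
        profiles=out,
        gene_ids=gene_ids,
        time_labels=time_labels,
        experiment_labels=experiment_labels,
    )
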