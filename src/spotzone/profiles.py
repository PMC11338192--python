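"""Zone-profiling statistics.

Signature-based tissue labeling, module scores (signature mean minus
expression-matched control mean), one-vs-rest Wilcoxon differential
expression on group-by-zone labels, and the per-zone/per-group median
summary tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix

__all__ = [
    "bh_adjust",
    "label_spots_by_signature",
    "module_score",
    "zone_group_key",
    "wilcoxon_one_vs_rest",
    "write_de_table",
    "gene_fc_summary",
    "signature_median_summary",
]


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    return multipletests(np.asarray(pvals), method="fdr_bh")[1]


def _signature_mean(norm: NormalizedMatrix, genes: Iterable[str], what: str) -> np.ndarray:
    index = {g: i for i, g in enumerate(norm.genes)}
    rows = [index[g] for g in genes if g in index]
    if not rows:
        raise ValueError(f"{what} signature has no genes in the measured universe")
    return np.asarray(norm.matrix[rows].mean(axis=0)).ravel()


def label_spots_by_signature(
    norm: NormalizedMatrix,
    tumor_sig: Sequence[str],
    parenchyma_sig: Sequence[str],
) -> np.ndarray:
    """Binary tissue class per spot from two marker signatures.

    A spot is called tumor (1) when the mean normalized expression of
    the tumor signature strictly exceeds that of the parenchyma
    signature; ties go to parenchyma (0) with a warning.
    """
    t = _signature_mean(norm, tumor_sig, "tumor")
    p = _signature_mean(norm, parenchyma_sig, "parenchyma")
    ties = t == p
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} spot(s) tie between signatures; classed as parenchyma"
        )
    return (t > p).astype(int)


def module_score(
    norm: NormalizedMatrix,
    signature: Sequence[str],
    nbin: int = 24,
    nctrl: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Per-spot module score of a gene signature.

    All genes are ranked by their average expression across spots and
    split into ``nbin`` equal-frequency bins.  For each signature gene,
    ``nctrl`` control genes are drawn from its bin with the seeded
    generator (with replacement when the bin is smaller than
    ``nctrl``).  The score is the mean expression of the signature
    genes minus the mean over all drawn controls (multiplicity kept).
    """
    n_genes = len(norm.genes)
    if nbin < 1 or nbin > n_genes:
        raise ValueError(f"nbin must be in [1, {n_genes}]")
    index = {g: i for i, g in enumerate(norm.genes)}
    sig_rows = [index[g] for g in signature if g in index]
    if not sig_rows:
        raise ValueError("signature has no genes in the measured universe")

    dense = norm.to_dense()
    avg = dense.mean(axis=1)
    # equal-frequency bins on the expression rank; ties and the in-bin draw
    # order resolve by gene name, so gene order in the matrix is irrelevant
    names = np.asarray(norm.genes)
    order = np.lexsort((names, avg))
    rank = np.empty(n_genes, dtype=int)
    rank[order] = np.arange(n_genes)
    bins = (rank * nbin) // n_genes
    bin_members = [
        np.where(bins == b)[0][np.argsort(names[bins == b], kind="stable")]
        for b in range(nbin)
    ]

    rng = np.random.default_rng(seed)
    control_rows: list[np.ndarray] = []
    for row in sig_rows:
        members = bin_members[bins[row]]
        replace = nctrl > len(members)
        control_rows.append(rng.choice(members, size=nctrl, replace=replace))
    controls = np.concatenate(control_rows)
    return dense[sig_rows].mean(axis=0) - dense[controls].mean(axis=0)


def zone_group_key(spots: pd.DataFrame) -> pd.Series:
    """Concatenate treatment group and zone: ``<group>_<zone>``.

    Splitting the key on the first underscore recovers (group, zone).
    """
    if spots["zone"].isna().any():
        bad = spots.loc[spots["zone"].isna(), "barcode"].tolist()
        raise ValueError(f"spots without a zone label: {bad}")
    return spots["group"].astype(str) + "_" + spots["zone"].astype(str)


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def wilcoxon_one_vs_rest(
    norm: NormalizedMatrix,
    labels: Sequence[str],
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum DE for every label.

    Per gene and label: rank-sum p (normal approximation with midrank
    tie correction and continuity correction; exact enumeration when
    both sides have at most ``exact_max_n`` spots), fold change
    ``avg_log2FC = log2((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1))``,
    and the percentage of spots with positive expression on each side.
    p-values are Benjamini-Hochberg adjusted within each label.
    """
    labels = np.asarray(labels)
    if len(labels) != norm.matrix.shape[1]:
        raise ValueError("labels length does not match number of spots")
    dense = norm.to_dense()
    n_genes, n = dense.shape
    expm1 = np.expm1(dense)
    positive = dense > 0

    ranks = scipy.stats.rankdata(dense, axis=1)
    ties = np.array([_tie_term(row) for row in dense])

    frames = []
    for label in pd.unique(labels):
        mask = labels == label
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            raise ValueError(f"label {label!r} leaves an empty group")

        m_in = expm1[:, mask].mean(axis=1)
        m_out = expm1[:, ~mask].mean(axis=1)
        lfc = np.log2((m_in + 1.0) / (m_out + 1.0))
        pct_in = 100.0 * positive[:, mask].mean(axis=1)
        pct_out = 100.0 * positive[:, ~mask].mean(axis=1)

        if n1 <= exact_max_n and n2 <= exact_max_n:
            pvals = np.array(
                [
                    scipy.stats.mannwhitneyu(
                        dense[g, mask], dense[g, ~mask],
                        alternative="two-sided",
                        method="exact" if ties[g] == 0 else "asymptotic",
                    ).pvalue
                    for g in range(n_genes)
                ]
            )
        else:
            u = ranks[:, mask].sum(axis=1) - n1 * (n1 + 1) / 2.0
            mean_u = n1 * n2 / 2.0
            var_u = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
            z[~np.isfinite(z)] = 0.0  # constant gene: no evidence either way
            pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
            pvals = np.minimum(pvals, 1.0)

        padj = bh_adjust(pvals)
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.genes,
                    "cluster": label,
                    "avg_log2FC": lfc,
                    "p_value": pvals,
                    "p_adjusted": padj,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """Write the DE table in the tab-separated dialect of the protocol."""
    out = pd.DataFrame(
        {
            "p_val": de["p_value"],
            "avg_log2FC": de["avg_log2FC"],
            "pct.1": de["pct_in"],
            "pct.2": de["pct_out"],
            "p_val_adj": de["p_adjusted"],
            "GeneID": de["gene"],
            "Cluster": de["cluster"],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _split_key(key: pd.Series) -> tuple[pd.Series, pd.Series]:
    parts = key.str.split("_", n=1, expand=True)
    return parts[0], parts[1]


def gene_fc_summary(de: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Median fold change of selected genes per zone and group.

    ``FC = 2 ** avg_log2FC``; medians are taken per (gene, label) and
    the per-gene minimum across the table is attached.  Genes absent
    from the DE table are dropped with a warning.
    """
    present = [g for g in genes if g in set(de["gene"])]
    absent = sorted(set(genes) - set(present))
    if absent:
        warnings.warn(f"genes absent from the DE table, omitted: {absent}")
    sub = de[de["gene"].isin(present)].copy()
    sub["FC"] = 2.0 ** sub["avg_log2FC"]
    med = (
        sub.groupby(["gene", "cluster"], sort=True)["FC"]
        .median()
        .rename("median")
        .reset_index()
    )
    mins = med.groupby("gene")["median"].min().rename("minimum")
    med = med.merge(mins, on="gene")
    med["group"], med["zone"] = _split_key(med["cluster"])
    return med.rename(columns={"gene": "name"})[
        ["name", "zone", "group", "median", "minimum"]
    ]


def signature_median_summary(
    scores: Mapping[str, np.ndarray], spots: pd.DataFrame
) -> pd.DataFrame:
    """Median module score per (signature, zone, group).

    ``scores`` maps signature names to per-spot score vectors aligned
    with ``spots`` (which must carry ``zone`` and ``group``).  The
    per-signature minimum median across all cells of the table is
    attached; empty (zone, group) cells yield no row.
    """
    frames = []
    for name, vec in scores.items():
        vec = np.asarray(vec)
        if len(vec) != len(spots):
            raise ValueError(f"scores for {name!r} are not aligned with spots")
        frames.append(
            pd.DataFrame(
                {
                    "name": name,
                    "zone": spots["zone"].to_numpy(),
                    "group": spots["group"].to_numpy(),
                    "score": vec,
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    med = (
        long.groupby(["name", "zone", "group"], sort=True)["score"]
        .median()
        .rename("median")
        .reset_index()
    )
    mins = med.groupby("name")["median"].min().rename("minimum")
    return med.merge(mins, on="name")[["name", "zone", "group", "median", "minimum"]]
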