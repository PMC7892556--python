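"""Subtype classification and stiffness differential expression.

PDX tumors carry human epithelium on mouse stroma, so hybridizing each
sample on both a human and a mouse array splits expression by compartment.
Two analyses are implemented:

* a Mesenchymal / Non-Mesenchymal subtype classifier: per-gene
  standardization within each dataset (mean 0, SD 1), merge on shared
  genes, hierarchical clustering (Euclidean distance, complete linkage) on
  a 36-gene signature split into halves correlated and anti-correlated with
  miR-200a, and a two-way dendrogram cut;
* stiffness differential expression on Log2+1 data: Student t-tests,
  unpaired between groups except center-vs-periphery within stiff tumors
  which is paired by tumor, filtered at P <= 0.05 and fold change > 1.2
  (no multiple-testing correction, by design; a Benjamini-Hochberg option
  exists as a clearly labeled extension).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ExpressionDataset",
    "SignatureSet",
    "SubtypeResult",
    "log2p1",
    "standardize_genes",
    "merge_standardized",
    "cluster_subtypes",
    "differential_expression",
    "filter_de",
    "de_contrast_suite",
]

logger = logging.getLogger(__name__)

SIGNATURE_SIZE = 36
DE_P_CUT = 0.05
DE_FC_CUT = 1.2


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with sample annotations.

    ``expr`` rows are genes, columns are samples; ``annotations`` is
    indexed by sample id with columns among {subtype, stiffness_class,
    region, tumor_id, compartment}.  ``log_scale`` flags whether the
    Log2+1 transform has been applied (at most once).
    """

    expr: pd.DataFrame
    annotations: pd.DataFrame
    log_scale: bool = False
    standardized: bool = False
    compartment: str = "NA"

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if not self.expr.columns.equals(self.annotations.index):
            if set(self.expr.columns) != set(self.annotations.index):
                raise ValueError("annotation index must match sample columns")
            self.annotations = self.annotations.loc[self.expr.columns]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching every annotation condition exactly."""
        sel = pd.Series(True, index=self.annotations.index)
        for col, value in conditions.items():
            sel &= self.annotations[col] == value
        return list(self.annotations.index[sel])


@dataclass(frozen=True)
class SignatureSet:
    """36-gene subtype signature split into miR-200a-correlated halves.

    ``correlated`` genes track miR-200a (higher in Non-Mesenchymal tumors);
    ``anticorrelated`` genes oppose it (stromal program, higher in
    Mesenchymal tumors).
    """

    correlated: tuple
    anticorrelated: tuple

    def __post_init__(self) -> None:
        genes = list(self.correlated) + list(self.anticorrelated)
        if len(set(genes)) != len(genes):
            raise ValueError("signature gene ids must be unique")
        if len(genes) != SIGNATURE_SIZE:
            raise ValueError(f"signature must contain exactly {SIGNATURE_SIZE} genes")
        if not self.correlated or not self.anticorrelated:
            raise ValueError("both signature halves must be non-empty")

    @property
    def genes(self) -> list[str]:
        return list(self.correlated) + list(self.anticorrelated)

    @classmethod
    def from_file(cls, path) -> "SignatureSet":
        """Read a signature list: one gene per line, with a
        ``#anticorrelated`` marker starting the second half."""
        correlated, anticorrelated = [], []
        bucket = correlated
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "anticorrelated" in line.lower():
                        bucket = anticorrelated
                    continue
                bucket.append(line)
        return cls(correlated=tuple(correlated), anticorrelated=tuple(anticorrelated))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# correlated with miR-200a\n")
            fh.write("\n".join(self.correlated) + "\n")
            fh.write("#anticorrelated\n")
            fh.write("\n".join(self.anticorrelated) + "\n")


@dataclass
class SubtypeResult:
    """Dendrogram, two-cluster cut and Mesenchymal/Non-Mesenchymal labels."""

    linkage_matrix: np.ndarray
    clusters: pd.Series          # sample -> {1, 2}
    labels: pd.Series            # sample -> {Mesenchymal, Non-Mesenchymal}


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log2p1(ds: ExpressionDataset) -> ExpressionDataset:
    """Log2+1 transform: x -> log2(x + 1); flips the scale flag."""
    if ds.log_scale:
        raise ValueError("dataset is already on log scale")
    if (ds.expr.to_numpy() < 0).any():
        raise ValueError("negative values on linear scale")
    return replace(ds, expr=np.log2(ds.expr + 1.0), log_scale=True)


def standardize_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each gene across samples (mean 0, sample SD 1).

    Zero-variance genes cannot be scaled; they are dropped with a logged
    warning.  Idempotent: a standardized dataset passes through unchanged.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples to standardize")
    sd = ds.expr.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped == ds.expr.shape[0]:
        raise ValueError("all genes have zero variance")
    if n_dropped:
        logger.warning("dropping %d zero-variance gene(s) during standardization",
                       n_dropped)
    expr = ds.expr.loc[keep]
    z = expr.sub(expr.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return replace(ds, expr=z, standardized=True)


def merge_standardized(a: ExpressionDataset, b: ExpressionDataset,
                       min_shared: int = SIGNATURE_SIZE) -> ExpressionDataset:
    """Concatenate two standardized datasets on their shared genes.

    Per-dataset standardization before merging is what removes platform
    batch effects; merging unstandardized data is refused.  A provenance
    column ``source_dataset`` records each sample's origin.
    """
    if b.n_samples == 0:
        return a
    if a.n_samples == 0:
        return b
    if not (a.standardized and b.standardized):
        raise ValueError("both datasets must be standardized before merging")
    shared = a.expr.index.intersection(b.expr.index)
    if len(shared) < min_shared:
        raise ValueError(f"insufficient gene overlap ({len(shared)} < {min_shared})")
    expr = pd.concat([a.expr.loc[shared], b.expr.loc[shared]], axis=1)
    ann_a = a.annotations.copy()
    ann_a["source_dataset"] = "A"
    ann_b = b.annotations.copy()
    ann_b["source_dataset"] = "B"
    ann = pd.concat([ann_a, ann_b])
    if expr.columns.duplicated().any():
        raise ValueError("duplicate sample ids across datasets")
    return ExpressionDataset(expr=expr, annotations=ann,
                             log_scale=a.log_scale, standardized=True,
                             compartment=a.compartment)


# ---------------------------------------------------------------------------
# Subtype classifier
# ---------------------------------------------------------------------------

def cluster_subtypes(ds: ExpressionDataset, signature: SignatureSet) -> SubtypeResult:
    """Hierarchical clustering on the 36-gene signature, cut in two.

    Samples are clustered on the signature submatrix with Euclidean
    distance and complete linkage; the dendrogram is cut into two clusters.
    The cluster with the higher mean expression of the anti-correlated
    (stromal, Mesenchymal-up) half is labeled Mesenchymal.
    """
    missing = [g for g in signature.genes if g not in ds.expr.index]
    if missing:
        raise ValueError(f"missing signature genes: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples to cluster")
    sub = ds.expr.loc[signature.genes]          # 36 x samples
    x = sub.to_numpy().T                        # samples x 36
    z = linkage(x, method="complete", metric="euclidean")
    clusters = pd.Series(fcluster(z, t=2, criterion="maxclust"),
                         index=ds.expr.columns, name="cluster")
    anti_mean = sub.loc[list(signature.anticorrelated)].mean(axis=0)
    cluster_means = anti_mean.groupby(clusters).mean()
    mes_cluster = int(cluster_means.idxmax())
    labels = clusters.map(lambda c: "Mesenchymal" if c == mes_cluster
                          else "Non-Mesenchymal").rename("subtype")
    return SubtypeResult(linkage_matrix=z, clusters=clusters, labels=labels)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def differential_expression(ds: ExpressionDataset,
                            group_a: list[str], group_b: list[str],
                            paired_by: str | None = None,
                            welch: bool = False,
                            bh: bool = False) -> pd.DataFrame:
    """Per-gene t-tests between two sample groups on log2 data.

    Unpaired Student t (equal variance) by default, Welch with
    ``welch=True``; ``paired_by`` names an annotation column (normally
    ``tumor_id``) whose values must pair group A and B samples one-to-one,
    switching to a paired t-test.  Returns one row per gene with t, p,
    mean log2 difference (A - B), fold change FC = 2^|difference|,
    direction and the P <= 0.05 & FC > 1.2 pass flag.  ``bh=True`` adds a
    Benjamini-Hochberg adjusted p and gates the pass flag on it; this is
    an extension, off by default.
    """
    if not ds.log_scale:
        raise ValueError("differential expression requires Log2+1 data")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = ds.expr[group_a].to_numpy()
    b = ds.expr[group_b].to_numpy()
    if paired_by is not None:
        keys_a = ds.annotations.loc[group_a, paired_by]
        keys_b = ds.annotations.loc[group_b, paired_by]
        if len(group_a) != len(group_b) or set(keys_a) != set(keys_b) \
                or keys_a.duplicated().any() or keys_b.duplicated().any():
            raise ValueError(f"incomplete pairing on {paired_by!r}")
        order = {k: i for i, k in enumerate(keys_b)}
        b = b[:, [order[k] for k in keys_a]]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat, p = stats.ttest_rel(a, b, axis=1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    delta = a.mean(axis=1) - b.mean(axis=1)
    fc = 2.0 ** np.abs(delta)
    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
    result = pd.DataFrame({
        "t": t_stat, "p": p, "mean_log2_difference": delta,
        "fold_change": fc, "direction": direction,
    }, index=ds.expr.index)
    p_gate = result["p"]
    if bh:
        result["p_adj"] = _benjamini_hochberg(result["p"].to_numpy())
        p_gate = result["p_adj"]
    result["passed"] = (p_gate <= DE_P_CUT) & (result["fold_change"] > DE_FC_CUT)
    result["passed"] = result["passed"].fillna(False)
    return result


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (extension; not part of the core filter)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def filter_de(result: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split passing genes into up- and down-regulated lists."""
    passing = result[result["passed"].astype(bool)]
    up = list(passing.index[passing["direction"] == "up"])
    down = list(passing.index[passing["direction"] == "down"])
    return up, down


def de_contrast_suite(human: ExpressionDataset,
                      mouse: ExpressionDataset,
                      welch: bool = False,
                      bh: bool = False) -> dict[str, pd.DataFrame]:
    """The six stiffness contrasts, per compartment.

    For each compartment dataset (human epithelium, mouse stroma):
    stiff-center vs soft and stiff-periphery vs soft (unpaired), and center
    vs periphery within stiff tumors (paired by tumor).  Stiff tumors
    lacking one region are dropped from the paired contrast with a logged
    warning.  Returns ``{contrast_name: DEResult table}``.
    """
    results: dict[str, pd.DataFrame] = {}
    for name, ds in (("epithelium", human), ("stroma", mouse)):
        ann = ds.annotations
        for col in ("stiffness_class", "region", "tumor_id"):
            if col not in ann.columns or ann[col].isna().any():
                raise ValueError(f"annotation column {col!r} incomplete in {name}")
        soft = ds.samples_where(stiffness_class="soft", region="center")
        stiff_c = ds.samples_where(stiffness_class="stiff", region="center")
        stiff_p = ds.samples_where(stiffness_class="stiff", region="periphery")
        results[f"{name}_stiff_center_vs_soft"] = differential_expression(
            ds, stiff_c, soft, welch=welch, bh=bh)
        results[f"{name}_stiff_periphery_vs_soft"] = differential_expression(
            ds, stiff_p, soft, welch=welch, bh=bh)
        tumors_c = set(ann.loc[stiff_c, "tumor_id"])
        tumors_p = set(ann.loc[stiff_p, "tumor_id"])
        complete = tumors_c & tumors_p
        dropped = (tumors_c | tumors_p) - complete
        if dropped:
            logger.warning("paired contrast (%s): dropping tumor(s) lacking one "
                           "region: %s", name, sorted(dropped))
        pc = [s for s in stiff_c if ann.loc[s, "tumor_id"] in complete]
        pp = [s for s in stiff_p if ann.loc[s, "tumor_id"] in complete]
        results[f"{name}_center_vs_periphery_stiff"] = differential_expression(
            ds, pc, pp, paired_by="tumor_id", welch=welch, bh=bh)
    return results
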