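"""Synthetic DE-experiment collections with planted structure.

The generator emulates, at the DE-table level, the statistical structure the
rest of the package assumes of real data: groups of experiments probing the
same biology share small p-values on the same genes.  Per cluster a disjoint
*signature* gene set is drawn; every experiment of the cluster gives those
genes fold changes around a signed effect size, while non-signature genes get
zero-mean noise.

The model is a calibrated small-replicate DE test with ``pseudo_n`` (= 6)
effective replicates and per-replicate noise ``noise_sd``: the observed fold
change of a gene with true effect δ is N(δ, noise_sd/√pseudo_n), and its
p-value is the two-sided normal tail of the standardized effect
(foldChange / noise_sd) · √pseudo_n.  Under the null (δ = 0) the statistic is
standard normal, so non-regulated genes — and every gene of a null
experiment — get exactly uniform p-values, as a well-calibrated test on real
data would, while signature genes share small p-values across a cluster.
baseMean is log-normal; each experiment drops a small random fraction of
genes so the union-plus-imputation paths are exercised.

GO annotations are generated with matching structure: *enriched* terms sample
most of their genes from one cluster's signature, background terms sample
uniformly.

Everything is driven by one integer seed; identical seeds give byte-identical
artifacts.  ``TruthLabels`` records the planted cluster labels, inverted
pairs and enriched terms, so tests never re-derive ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .collection import ExperimentCollection, build_collection
from .errors import ValidationError
from .goterms import GoAnnotation, GoTerm
from .io import DataDictionary, Dimension, Experiment


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic collection.

    Defaults: 3 clusters × 5 experiments plus 3 null experiments over 2000
    genes, effect size 1.0 (mean |log2 fold change| of signature genes),
    noise SD 0.5, signatures covering 10% of genes.
    """

    n_genes: int = 2000
    n_clusters: int = 3
    experiments_per_cluster: int = 5
    n_null_experiments: int = 3
    effect_size: float = 1.0
    signature_fraction: float = 0.10
    noise_sd: float = 0.5
    pseudo_n: int = 6
    missing_fraction: float = 0.02
    n_terms: int = 60
    term_size_range: tuple[int, int] = (10, 50)
    enriched_term_fraction: float = 0.3
    enriched_purity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_clusters", "experiments_per_cluster", "n_terms", "pseudo_n"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_null_experiments < 0:
            raise ValidationError("n_null_experiments must be >= 0")
        for name in ("signature_fraction", "enriched_term_fraction", "enriched_purity"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValidationError("missing_fraction must lie in [0, 1)")
        if self.noise_sd <= 0 or self.effect_size <= 0:
            raise ValidationError("effect_size and noise_sd must be positive")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValidationError("term sizes cannot exceed n_genes")
        sig = int(round(self.signature_fraction * self.n_genes))
        if sig < 1 or sig * self.n_clusters > self.n_genes:
            raise ValidationError(
                "infeasible sizes: clusters need disjoint signatures of "
                f"{sig} genes each within {self.n_genes} genes"
            )


@dataclass
class TruthLabels:
    """Planted ground truth of a generated collection and annotation."""

    cluster_of: dict  # experiment id -> cluster index, or None for nulls
    signatures: dict  # cluster index -> (tuple of gene ids, tuple of signs ±1)
    inverted_pairs: list = field(default_factory=list)  # (original id, inverted id)
    enriched_in: dict = field(default_factory=dict)  # term id -> cluster index or None

    @property
    def clustered_ids(self) -> list:
        return [e for e, c in self.cluster_of.items() if c is not None]


_DICT = DataDictionary(
    (
        Dimension("EnsemblID", "identifier", "Ensembl gene identifier"),
        Dimension("geneName", "categorical", "gene symbol"),
        Dimension("baseMean", "numeric", "mean normalized expression"),
        Dimension("foldChange", "numeric", "log2 fold change between conditions"),
        Dimension("pValue", "numeric", "DE test p-value"),
    )
)


def _pvalues_from_fold(fc: np.ndarray, noise_sd: float, pseudo_n: int) -> np.ndarray:
    z = np.abs(fc) / noise_sd * math.sqrt(pseudo_n)
    return np.clip(2.0 * norm.sf(z), 0.0, 1.0)


def generate_collection(config: SynthConfig) -> tuple[ExperimentCollection, TruthLabels]:
    """Generate a collection with planted similarity clusters and null experiments."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"ENSSYNG{i:011d}" for i in range(n)], dtype=object)
    names = np.array([f"Gene{i}" for i in range(n)], dtype=object)

    sig_size = int(round(config.signature_fraction * n))
    perm = rng.permutation(n)
    signatures: dict[int, tuple[tuple, tuple]] = {}
    sig_idx: dict[int, np.ndarray] = {}
    sig_sign: dict[int, np.ndarray] = {}
    for c in range(config.n_clusters):
        idx = np.sort(perm[c * sig_size:(c + 1) * sig_size])
        signs = rng.choice([-1.0, 1.0], size=sig_size)
        sig_idx[c] = idx
        sig_sign[c] = signs
        signatures[c] = (tuple(genes[idx].tolist()), tuple(int(s) for s in signs))

    experiments = []
    cluster_of: dict[str, int | None] = {}

    def make_experiment(eid: str, title: str, visibility: str,
                        fc: np.ndarray, p: np.ndarray) -> Experiment:
        base = rng.lognormal(mean=3.0, sigma=1.5, size=n)
        frame = pd.DataFrame(
            {
                "EnsemblID": genes,
                "geneName": names,
                "baseMean": base,
                "foldChange": fc,
                "pValue": p,
            }
        )
        n_drop = int(round(config.missing_fraction * n))
        if n_drop:
            drop = rng.choice(n, size=n_drop, replace=False)
            frame = frame.drop(index=drop).reset_index(drop=True)
        return Experiment(
            id=eid, title=title, visibility=visibility, icon="box",
            data=frame, dictionary=_DICT,
        )

    fc_se = config.noise_sd / math.sqrt(config.pseudo_n)
    for c in range(config.n_clusters):
        for r in range(config.experiments_per_cluster):
            fc = rng.normal(0.0, fc_se, size=n)
            fc[sig_idx[c]] = rng.normal(
                sig_sign[c] * config.effect_size, fc_se
            )
            p = _pvalues_from_fold(fc, config.noise_sd, config.pseudo_n)
            eid = f"cluster{c}_rep{r}"
            visibility = "private" if c == 0 else "public"
            exp = make_experiment(eid, f"Cluster {c} replicate {r}", visibility, fc, p)
            experiments.append(exp)
            cluster_of[eid] = c

    for j in range(config.n_null_experiments):
        # an all-null comparison: p-values are exactly uniform by calibration
        fc = rng.normal(0.0, fc_se, size=n)
        p = _pvalues_from_fold(fc, config.noise_sd, config.pseudo_n)
        eid = f"null{j}"
        exp = make_experiment(eid, f"Null experiment {j}", "public", fc, p)
        experiments.append(exp)
        cluster_of[eid] = None

    collection = build_collection(experiments)
    truth = TruthLabels(cluster_of=cluster_of, signatures=signatures)
    return collection, truth


def invert_experiment(experiment: Experiment, suffix: str = "_inv") -> Experiment:
    """The same comparison run in the opposite direction.

    Fold changes are negated exactly; p-values, baseMean and the gene set are
    untouched, so the inverted twin is indistinguishable from the original on
    the p-value-based similarity overview.  Applying it twice restores the
    original values.
    """
    for dim in ("foldChange", "pValue"):
        if dim not in experiment.dictionary.names:
            raise ValidationError(f"experiment lacks dimension {dim!r}")
    data = experiment.data.copy()
    data["foldChange"] = -data["foldChange"].to_numpy(dtype=float)
    new_id = (
        experiment.id[: -len(suffix)]
        if experiment.id.endswith(suffix)
        else experiment.id + suffix
    )
    return replace(experiment, id=new_id, data=data)


def generate_go_annotation(
    config: SynthConfig, truth: TruthLabels
) -> tuple[GoAnnotation, TruthLabels]:
    """Generate a GO annotation whose enriched terms track the planted signatures.

    A fraction of terms is *enriched*: at least ``enriched_purity`` of their
    genes come from one cluster's signature, assigned round-robin across
    clusters; the rest are background terms sampled uniformly from the whole
    gene universe.  Term sizes are uniform over ``term_size_range``.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = config.n_genes
    genes = [f"ENSSYNG{i:011d}" for i in range(n)]
    lo, hi = config.term_size_range
    n_enriched = int(round(config.enriched_term_fraction * config.n_terms))
    clusters = sorted(truth.signatures)
    if n_enriched and not clusters:
        raise ValidationError("cannot plant enriched terms without cluster signatures")

    terms: dict[str, GoTerm] = {}
    enriched_in: dict[str, int | None] = {}
    for t in range(config.n_terms):
        tid = f"GO:S{t:06d}"
        size = int(rng.integers(lo, hi + 1))
        if t < n_enriched:
            c = clusters[t % len(clusters)]
            sig = list(truth.signatures[c][0])
            n_sig = min(int(math.ceil(config.enriched_purity * size)), len(sig), size)
            member = list(rng.choice(sig, size=n_sig, replace=False))
            rest = [g for g in genes if g not in set(member)]
            n_bg = size - n_sig
            if n_bg:
                member += list(rng.choice(rest, size=n_bg, replace=False))
            name = f"synthetic enriched process {t} (cluster {c})"
            enriched_in[tid] = c
        else:
            member = list(rng.choice(genes, size=size, replace=False))
            name = f"synthetic background process {t}"
            enriched_in[tid] = None
        terms[tid] = GoTerm(tid, name, f"synthetic term {t}", frozenset(member))

    index: dict[str, set] = {}
    for tid, term in terms.items():
        for g in term.genes:
            index.setdefault(g, set()).add(tid)
    annotation = GoAnnotation(terms, {g: frozenset(t) for g, t in index.items()})
    truth.enriched_in = enriched_in
    return annotation, truth
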