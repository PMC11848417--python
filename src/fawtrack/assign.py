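"""Supervised individual assignment with Monte-Carlo cross-validation.

The procedure mirrors assignment-test practice for tracing invasive
populations to candidate sources: in each of many resamples a fraction
of every source group is drawn as a training set; near-monomorphic loci
are removed (pooled major-allele frequency >= a variance threshold);
remaining loci are ranked by among-source Weir & Cockerham F_ST
computed on the training subset only, and a top fraction is kept; a
linear SVM fit on training dosages then classifies both the held-out
source individuals (cross-validation accuracy) and the query
individuals. Membership of a query individual in a source group is the
fraction of resamples assigning it there.

Locus selection and imputation statistics are computed strictly on the
training subset, so no information from held-out or query individuals
leaks into the model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from fawtrack.core import GenotypeMatrix
from fawtrack.popgen import per_locus_fst

log = logging.getLogger(__name__)


@dataclass
class AssignmentConfig:
    """Resampling design: training fractions × locus fractions, each
    cell resampled ``n_resamples`` times."""

    train_props: tuple[float, ...] = (0.5, 0.7, 0.9)
    loci_props: tuple[float, ...] = (0.6, 0.8, 1.0)
    n_resamples: int = 1000
    variance_threshold: float = 0.95
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        for f in (*self.train_props, *self.loci_props):
            if not 0.0 < f <= 1.0:
                raise ValueError("fractions must lie in (0, 1]")


@dataclass
class AssignmentResult:
    groups: list[str]
    test_samples: list[str]
    membership: pd.DataFrame       # test x group, resample fractions
    mean_probability: pd.DataFrame # test x group, mean class probability
    final: pd.Series               # test -> argmax group
    accuracy: dict[tuple[float, float], float]  # (train, loci) -> CV accuracy
    n_resamples: int
    skipped_cells: list[tuple[float, float]] = field(default_factory=list)


def variance_prefilter(
    training: GenotypeMatrix, threshold: float = 0.95
) -> np.ndarray:
    """Indices of loci whose pooled major-allele frequency is below the
    threshold (near-monomorphic loci removed)."""
    dos = training.dosages
    n_called = (~np.isnan(dos)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n_called)
    major = np.maximum(p, 1.0 - p)
    keep = np.flatnonzero((n_called > 0) & (major < threshold))
    if keep.size == 0:
        raise ValueError("variance pre-filter removed every locus")
    return keep


def rank_loci_by_fst(
    training: GenotypeMatrix, groups: list[str], prop: float
) -> np.ndarray:
    """Indices of the top ``ceil(prop * L)`` loci by among-group F_ST
    on the training individuals; ties and NaNs rank by locus order."""
    if prop <= 0.0:
        raise ValueError("prop must be positive")
    if len(groups) < 2:
        raise ValueError("need at least 2 source groups")
    fst = per_locus_fst(training, groups)
    fst = np.where(np.isfinite(fst), fst, -np.inf)
    n_top = min(math.ceil(prop * training.n_loci), training.n_loci)
    order = np.argsort(-fst, kind="stable")      # stable -> locus-order ties
    return np.sort(order[:n_top])


def _impute(dos: np.ndarray, col_means: np.ndarray) -> np.ndarray:
    out = np.where(np.isnan(dos), col_means, dos)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def monte_carlo_assign(
    matrix: GenotypeMatrix,
    source_groups: list[str],
    test_samples: list[str],
    config: AssignmentConfig | None = None,
) -> AssignmentResult:
    """Run the full resampling design and aggregate memberships.

    ``source_groups`` are population labels in the matrix;
    ``test_samples`` are sample names disjoint from the source
    individuals. Cells where a group's training draw would be smaller
    than 2 individuals are skipped with a warning.
    """
    config = config or AssignmentConfig()
    group_rows = {g: matrix.pop_indices(g) for g in source_groups}
    for g, rows in group_rows.items():
        if rows.size < 2:
            raise ValueError(f"source group {g!r} has fewer than 2 individuals")
    test_rows = np.asarray([matrix.sample_index(s) for s in test_samples], dtype=int)
    source_all = np.concatenate(list(group_rows.values()))
    if np.intersect1d(test_rows, source_all).size:
        raise ValueError("test individuals must be disjoint from source groups")

    rng = np.random.default_rng(config.seed)
    k = len(source_groups)
    membership_counts = np.zeros((len(test_samples), k))
    prob_sums = np.zeros((len(test_samples), k))
    n_used = 0
    accuracy: dict[tuple[float, float], float] = {}
    skipped: list[tuple[float, float]] = []

    for tp in config.train_props:
        for lp in config.loci_props:
            sizes = {g: int(round(tp * rows.size)) for g, rows in group_rows.items()}
            if any(s < 2 for s in sizes.values()):
                log.warning("cell (train=%.2f, loci=%.2f) skipped: group too small", tp, lp)
                skipped.append((tp, lp))
                continue
            cell_acc = []
            for _ in range(config.n_resamples):
                train_idx, heldout_idx, labels, ho_labels = [], [], [], []
                for g, rows in group_rows.items():
                    picked = rng.choice(rows, size=sizes[g], replace=False)
                    rest = np.setdiff1d(rows, picked)
                    train_idx.extend(picked)
                    labels.extend([g] * picked.size)
                    heldout_idx.extend(rest)
                    ho_labels.extend([g] * rest.size)
                train_idx = np.asarray(train_idx)
                train = matrix.take_samples(train_idx)
                train.pop_labels = {
                    s: g for s, g in zip(train.samples, labels)
                }
                try:
                    keep = variance_prefilter(train, config.variance_threshold)
                except ValueError:
                    continue
                sub = train.take_loci(keep)
                top = rank_loci_by_fst(sub, source_groups, lp)
                loci = keep[top]

                Xt = matrix.dosages[np.ix_(train_idx, loci)]
                with np.errstate(invalid="ignore"):
                    col_means = np.nanmean(Xt, axis=0)
                col_means = np.where(np.isfinite(col_means), col_means, 1.0)
                clf = SVC(kernel="linear", C=config.svm_c,
                          decision_function_shape="ovr")
                clf.fit(_impute(Xt, col_means), labels)

                if heldout_idx:
                    Xh = _impute(
                        matrix.dosages[np.ix_(np.asarray(heldout_idx), loci)],
                        col_means,
                    )
                    cell_acc.append(
                        float(np.mean(clf.predict(Xh) == np.asarray(ho_labels)))
                    )
                if test_rows.size:
                    Xq = _impute(matrix.dosages[np.ix_(test_rows, loci)], col_means)
                    margins = clf.decision_function(Xq)
                    if margins.ndim == 1:  # binary: margin toward classes_[1]
                        margins = np.column_stack([-margins, margins])
                    probs = _softmax(margins)
                    pred = clf.predict(Xq)
                    cls_order = [list(clf.classes_).index(g) for g in source_groups]
                    prob_sums += probs[:, cls_order]
                    for qi, g in enumerate(pred):
                        membership_counts[qi, source_groups.index(g)] += 1
                n_used += 1
            if cell_acc:
                accuracy[(tp, lp)] = float(np.mean(cell_acc))

    if n_used == 0:
        raise ValueError("every configuration cell was skipped")
    membership = pd.DataFrame(
        membership_counts / n_used, index=test_samples, columns=source_groups
    )
    mean_prob = pd.DataFrame(
        prob_sums / n_used, index=test_samples, columns=source_groups
    )
    final = membership.idxmax(axis=1) if test_samples else pd.Series(dtype=object)
    return AssignmentResult(
        groups=list(source_groups),
        test_samples=list(test_samples),
        membership=membership,
        mean_probability=mean_prob,
        final=final,
        accuracy=accuracy,
        n_resamples=n_used,
        skipped_cells=skipped,
    )


def assignment_report(result: AssignmentResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual membership table plus group-level summary.

    The first frame has one row per query individual: membership
    fraction per source group, the final call, and the resample count.
    The second gives the fraction of query individuals finally assigned
    to each source group.
    """
    per_ind = result.membership.copy()
    per_ind["final"] = result.final
    per_ind["n_resamples"] = result.n_resamples
    per_ind.index.name = "individual"
    if len(result.test_samples):
        frac = (
            result.final.value_counts(normalize=True)
            .reindex(result.groups, fill_value=0.0)
        )
    else:
        frac = pd.Series(0.0, index=result.groups)
    summary = pd.DataFrame(
        {"group": result.groups, "fraction_assigned": frac.values}
    )
    return per_ind, summary
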