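"""Group-level motion QC: the classical QC-FC benchmark and cohort summaries.

QC-FC correlates, for every edge, the functional connectivity value with the
subjects' mean framewise displacement across the cohort; edges whose
correlation is significant are flagged as motion corrupted for the group.
The metric presumes that motion-induced FC inflation varies across subjects
— when contamination saturates FC for nearly everyone (the ceiling effect
typical of fetal cohorts), edge-wise FC varies little with mean FD and QC-FC
approaches its chance level even though every subject is corrupted. The
subject-level statistic (see :mod:`fetalqc.qc_subject`) does not share this
failure mode; the contrast between the two is itself a diagnostic.

Cross-subject summaries of the subject-level metric (median / IQR of the
per-subject corrupted fraction per denoising strategy) and pooled
distance-dependence (Spearman rank correlation of edge-level FC-FD
correlations against subject-specific inter-regional distances) are also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats as _stats
from sklearn.base import BaseEstimator

from .qc_subject import SubjectQCReport

__all__ = [
    "GroupTable",
    "QCFCBenchmark",
    "qcfc",
    "group_summary",
    "pooled_distance_dependence",
]


@dataclass
class GroupTable:
    """Cohort container with consistent edge ordering across subjects.

    ``subjects`` is a list of dicts with keys ``subject_id``, ``mean_fd``
    (mm), ``fc_vector`` (per-edge FC), ``edge_distances`` (per-edge mm,
    subject-specific) and optionally ``qc_report``
    (:class:`~fetalqc.qc_subject.SubjectQCReport`).
    """

    subjects: list[dict]

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise ValueError("empty cohort")
        n_edges = {len(np.atleast_1d(s["fc_vector"])) for s in self.subjects}
        if len(n_edges) != 1:
            raise ValueError("inconsistent edge counts across subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def fc_matrix(self) -> NDArray[np.float64]:
        return np.vstack([np.asarray(s["fc_vector"], float) for s in self.subjects])

    @property
    def mean_fd(self) -> NDArray[np.float64]:
        return np.array([float(s["mean_fd"]) for s in self.subjects])


class QCFCBenchmark(BaseEstimator):
    """Classical group-level QC-FC estimator.

    ``fit(X, y)`` takes ``X`` = (n_subjects, n_edges) FC matrix and ``y`` =
    per-subject mean FD. Fitted attributes: per-edge ``r_`` and ``p_``
    (Pearson by default, Spearman optional), and ``n_significant_`` at
    ``alpha`` (uncorrected, the conventional reporting).
    """

    def __init__(self, alpha: float = 0.05, method: str = "pearson"):
        self.alpha = alpha
        self.method = method

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n_subjects, n_edges); y per-subject mean FD")
        n = X.shape[0]
        if n < 3:
            raise ValueError("QC-FC needs >= 3 subjects")
        if y.std() == 0:
            raise ValueError("mean FD has zero variance across subjects")
        if self.method == "spearman":
            Xr = np.apply_along_axis(_stats.rankdata, 0, X)
            yr = _stats.rankdata(y)
        elif self.method == "pearson":
            Xr, yr = X, y
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        Xc = Xr - Xr.mean(axis=0)
        yc = yr - yr.mean()
        den = np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * yc[:, None]).sum(axis=0) / den
        # edges whose FC does not vary across subjects are undefined
        constant = np.all(Xr == Xr[0], axis=0)
        r[constant | (den == 0)] = np.nan
        df = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = 2.0 * _stats.t.sf(np.abs(t), df)
        p[np.abs(r) >= 1.0] = 0.0
        self.r_ = r
        self.p_ = p
        self.n_significant_ = int(np.nansum(p < self.alpha))
        self.n_edges_ = X.shape[1]
        return self


def qcfc(
    group: GroupTable, alpha: float = 0.05, method: str = "pearson"
) -> tuple[pd.DataFrame, int]:
    """Per-edge QC-FC correlations and the significant-edge count.

    Returns a DataFrame with columns ``r`` and ``p`` (one row per edge) and
    the number of edges significant at ``alpha`` (uncorrected).
    """
    est = QCFCBenchmark(alpha=alpha, method=method).fit(group.fc_matrix, group.mean_fd)
    return pd.DataFrame({"r": est.r_, "p": est.p_}), est.n_significant_


def group_summary(
    reports_by_strategy: dict[str, list[SubjectQCReport]],
    min_windows: int = 4,
) -> pd.DataFrame:
    """Median and IQR of per-subject corrupted fractions for each strategy.

    Subjects whose report flags degenerate input, or whose connections are
    *all* corrupted (the signature of a series left too short by censoring),
    are flagged and the summary is reported both with and without them.
    """
    rows = []
    for strategy, reports in reports_by_strategy.items():
        fracs = np.array([r.frac_corrupted for r in reports], dtype=float)
        flagged = np.array(
            [r.fd_degenerate or (np.isfinite(r.frac_corrupted) and r.frac_corrupted >= 1.0)
             for r in reports]
        )
        ok = np.isfinite(fracs)
        kept = ok & ~flagged
        def _med_iqr(v):
            if v.size == 0:
                return np.nan, np.nan
            q1, q3 = np.percentile(v, [25, 75])
            return float(np.median(v)), float(q3 - q1)
        med_all, iqr_all = _med_iqr(fracs[ok])
        med_kept, iqr_kept = _med_iqr(fracs[kept])
        rows.append(
            {
                "strategy": strategy,
                "n_subjects": int(ok.sum()),
                "n_flagged": int(flagged.sum()),
                "median_frac_corrupted": med_all,
                "iqr_frac_corrupted": iqr_all,
                "median_frac_corrupted_excl": med_kept,
                "iqr_frac_corrupted_excl": iqr_kept,
            }
        )
    return pd.DataFrame(rows).set_index("strategy")


def pooled_distance_dependence(group: GroupTable) -> tuple[float, float]:
    """Spearman rho between pooled edge distances and FC-FD correlations.

    Distances are subject-specific (fetal brain size varies with
    gestational age); the (distance, r) pairs of all subjects are pooled
    before ranking. Ties get average ranks (scipy default).
    """
    dists, rs = [], []
    for s in group.subjects:
        rep: SubjectQCReport | None = s.get("qc_report")
        if rep is None:
            raise ValueError(f"subject {s.get('subject_id')} lacks a qc_report")
        d = np.array([e.distance for e in rep.edges], dtype=float)
        r = np.array([e.r for e in rep.edges], dtype=float)
        ok = np.isfinite(d) & np.isfinite(r)
        dists.append(d[ok])
        rs.append(r[ok])
    d = np.concatenate(dists)
    r = np.concatenate(rs)
    if d.size < 3:
        raise ValueError("not enough pooled edges for a rank correlation")
    rho, p = _stats.spearmanr(d, r)
    return float(rho), float(p)
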