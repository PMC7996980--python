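"""DIC computation and six-way model ranking.

The deviance information criterion trades posterior goodness of fit
against model complexity:

    pD  = Dbar - D(theta_bar)        (effective number of parameters)
    DIC = Dbar + pD = D(theta_bar) + 2*pD

where ``Dbar`` is the posterior mean deviance and ``D(theta_bar)`` the
deviance at the posterior mean of the parameters, taken in the
initial-condition parameterisation (see :func:`compute_dic` for why).
DICs are pooled across independently fitted subjects by summation
(deviance is additive over independent likelihoods); the variant with the
lowest pooled DIC is selected, with ties broken toward the lower variant
id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd

from .inference import (
    PosteriorChains,
    SubjectDataset,
    deviance,
    free_parameters,
    summarize,
)

__all__ = [
    "DICResult",
    "ModelComparisonTable",
    "dic_from_deviances",
    "compute_dic",
    "select_variant",
    "rank_models",
]

logger = logging.getLogger("exminmod")

#: a variant is flagged when the cross-subject median CV of any free
#: parameter exceeds this fraction
CV_CRITERION = 1.0


@dataclass(frozen=True)
class DICResult:
    """DIC decomposition for one model/dataset combination."""

    d_bar: float
    d_at_mean: float
    p_d: float
    dic: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_d):
            raise ValueError("pD must be finite")


def dic_from_deviances(deviances: np.ndarray, d_at_mean: float) -> DICResult:
    """Assemble the DIC decomposition from raw deviances.

    Both identities DIC = Dbar + pD and DIC = D(theta_bar) + 2*pD hold by
    construction. pD can come out negative under poor mixing or strongly
    non-Gaussian posteriors; that is logged, not rejected.
    """
    deviances = np.asarray(deviances, dtype=float)
    if deviances.size == 0:
        raise ValueError("empty deviance array")
    if not np.isfinite(d_at_mean):
        raise ValueError(
            f"deviance at the posterior mean is not finite ({d_at_mean!r})"
        )
    d_bar = float(np.mean(deviances))
    p_d = d_bar - float(d_at_mean)
    if p_d < 0:
        logger.warning("negative pD (%.3f); chain may be poorly mixed", p_d)
    return DICResult(d_bar=d_bar, d_at_mean=float(d_at_mean), p_d=p_d, dic=d_bar + p_d)


def compute_dic(chains: PosteriorChains, data: SubjectDataset, **kwargs) -> DICResult:
    """DIC for one fitted subject, re-evaluating the model at the posterior mean.

    The plug-in point is taken in the initial-condition parameterisation
    (geometric means of G0, p1, p2, p3, e1, e2; see
    :meth:`PosteriorChains.posterior_mean_parameters`). The data pin the
    initial glucose G0 tightly while leaving wide curved ridges in the raw
    parameters, so coordinate means taken on the natural (or even the log)
    scale fall off the data-constrained manifold and produce large spurious
    negative pD; in the initial-condition coordinates the posterior is
    near-Gaussian and the plug-in deviance is well behaved.
    """
    params_bar = chains.posterior_mean_parameters(scale="init")
    d_at_mean = deviance(params_bar, data, **kwargs)
    if not np.isfinite(d_at_mean):
        raise ValueError(
            "deviance at the posterior mean is not finite for subject "
            f"{chains.subject_id!r}, variant {chains.variant}"
        )
    return dic_from_deviances(chains.deviance, d_at_mean)


def select_variant(pooled_dic: Mapping[int, float]) -> int:
    """Variant with the lowest pooled DIC; ties break to the lower id."""
    if not pooled_dic:
        raise ValueError("no pooled DICs supplied")
    best = min(sorted(pooled_dic), key=lambda v: (pooled_dic[v], v))
    return int(best)


@dataclass
class ModelComparisonTable:
    """Six-way comparison: pooled DICs, cross-subject parameter summaries, winner."""

    pooled_dic: Dict[int, float]
    per_subject_dic: pd.DataFrame  # index subject, columns variant
    parameter_summary: pd.DataFrame  # index (variant, param), median/q25/q75
    selected_variant: int
    cv_flags: Dict[int, List[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per variant: Gp0, p1, p2, p3, e1, e2 medians (IQR) + DIC."""
        rows = []
        for variant in sorted(self.pooled_dic):
            row: Dict[str, object] = {"model": variant}
            for name in ("Gp0", "p1", "p2", "p3", "e1", "e2"):
                key = (variant, name)
                if key in self.parameter_summary.index:
                    s = self.parameter_summary.loc[key]
                    row[name] = s["median"]
                    row[f"{name}_q25"] = s["q25"]
                    row[f"{name}_q75"] = s["q75"]
                else:
                    row[name] = np.nan
                    row[f"{name}_q25"] = np.nan
                    row[f"{name}_q75"] = np.nan
            row["DIC"] = self.pooled_dic[variant]
            row["cv_flagged"] = ";".join(self.cv_flags.get(variant, []))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_models(
    per_subject_chains: Mapping[int, Mapping[str, PosteriorChains]],
    datasets: Mapping[str, SubjectDataset],
    **kwargs,
) -> ModelComparisonTable:
    """Rank the fitted variants on a common subject set.

    ``per_subject_chains`` maps variant -> subject_id -> chains; every
    variant must cover every subject in ``datasets`` (missing fits raise an
    error naming the gaps).
    """
    subjects = sorted(datasets)
    gaps = [
        (variant, sid)
        for variant in sorted(per_subject_chains)
        for sid in subjects
        if sid not in per_subject_chains[variant]
    ]
    if gaps:
        listing = ", ".join(f"variant {v}: subject {s!r}" for v, s in gaps)
        raise ValueError(f"missing fits: {listing}")
    if not per_subject_chains:
        raise ValueError("no fitted variants supplied")

    pooled: Dict[int, float] = {}
    per_subject = pd.DataFrame(index=subjects, columns=sorted(per_subject_chains), dtype=float)
    summary_rows = {}
    cv_flags: Dict[int, List[str]] = {}

    for variant in sorted(per_subject_chains):
        names = free_parameters(variant)
        medians: Dict[str, List[float]] = {n: [] for n in names}
        cvs: Dict[str, List[float]] = {n: [] for n in names}
        total = 0.0
        for sid in subjects:
            chains = per_subject_chains[variant][sid]
            result = compute_dic(chains, datasets[sid], **kwargs)
            per_subject.loc[sid, variant] = result.dic
            total += result.dic
            summ = summarize(chains)
            for n in names:
                medians[n].append(summ.median(n))
                cvs[n].append(summ.cv(n))
        pooled[variant] = total
        for n in names:
            q25, med, q75 = np.percentile(medians[n], [25, 50, 75])
            summary_rows[(variant, n)] = {
                "median": float(med),
                "q25": float(q25),
                "q75": float(q75),
                "median_cv": float(np.median(cvs[n])),
            }
        flagged = [
            n for n in names if summary_rows[(variant, n)]["median_cv"] > CV_CRITERION
        ]
        if flagged:
            cv_flags[variant] = flagged
            logger.warning(
                "variant %d fails the CV criterion (>100%%) for: %s",
                variant,
                ", ".join(flagged),
            )

    table = pd.DataFrame(summary_rows).T
    table.index = pd.MultiIndex.from_tuples(table.index, names=["variant", "param"])
    return ModelComparisonTable(
        pooled_dic=pooled,
        per_subject_dic=per_subject,
        parameter_summary=table,
        selected_variant=select_variant(pooled),
        cv_flags=cv_flags,
    )
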