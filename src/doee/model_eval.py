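"""Model SI's dependence on lesion burden across scans and compare fits.

Four competing models of the per-scan similarity index SI as a function of
mean total area (MTA) are evaluated on a common scan set:

========= ==== =======================================================
model     k    form
========= ==== =======================================================
mean      1    SI = c
linear    2    SI = a + b MTA
quadratic 3    SI = a + b MTA + c MTA^2
doee      2    SI = 1 - meanOER/2 - meanDE / (2 MTA)
========= ==== =======================================================

The DOEE model is *not* least-squares optimized: meanDE and meanOER are
the arithmetic means of the per-scan detection error and outline error
rate, so its reported residual sum of squares is conservative relative to
a free 2-parameter fit.  Models are ranked by the finite-sample-corrected
Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),

comparable only within a fixed scan set, and by the relative likelihood
exp((AICc_min - AICc_i)/2).

The usage mirrors statsmodels: build :class:`SimilarityBurdenModel` from
per-scan records or a DataFrame, call :meth:`~SimilarityBurdenModel.fit`,
and read estimates, diagnostics and the correlation battery off the
returned :class:`StudyFit` results object (``summary()`` prints a table).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .doee_metrics import ScanAgreement, si_estimate
from .errors import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "FittedModel",
    "SimilarityBurdenModel",
    "StudyFit",
    "fit_study",
    "aicc",
    "relative_likelihood",
    "correlation_battery",
    "spearman",
]

MODEL_NAMES = ("mean", "linear", "quadratic", "doee")
#: free quantities per model: mean SI; intercept+slope; three polynomial
#: coefficients; (meanDE, meanOER).  An error-variance parameter would add
#: +1 to every model and cancel in comparisons.
MODEL_K = {"mean": 1, "linear": 2, "quadratic": 3, "doee": 2}


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike criterion from a Gaussian residual sum of squares."""
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n={n} <= k+1={k + 1}")
    if rss < 0:
        raise DomainError("RSS must be non-negative")
    if rss == 0:
        logger.warning("RSS = 0: AICc reported as -inf (perfect fit)")
        return -math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def relative_likelihood(aicc_values: Sequence[float]) -> np.ndarray:
    """exp((min - AICc_i)/2) for each model; the best model gets 1."""
    vals = np.asarray(aicc_values, dtype=float)
    if np.sum(np.isfinite(vals) | np.isneginf(vals)) < 2:
        raise DomainError("need at least two AICc values to compare")
    best = vals.min()
    if np.isneginf(best):
        return np.where(np.isneginf(vals), 1.0, 0.0)
    with np.errstate(over="ignore"):
        return np.exp((best - vals) / 2.0)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with a t-approximation p for n >= 10 and an exact
    permutation p (two-sided, all n! rank orders) below.  Ties get average
    ranks.  Returns (nan, nan) for a constant column."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("Spearman correlation undefined for a constant column")
        return math.nan, math.nan
    if n >= 10:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho = float((rx_c * ry_c).sum() / denom)
    perms = np.array(list(itertools.permutations(ry_c)))
    rho_perm = perms @ rx_c / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def correlation_battery(
    per_scan: Sequence[ScanAgreement],
    mean_de: float | None = None,
    mean_oer: float | None = None,
) -> dict:
    """The study's correlation checks.

    Spearman rank correlations of MTA against DE, OE, OER and SI (rank
    correlation because SI's dependence on MTA is explicitly non-linear),
    plus Pearson correlations of observed SI against the DOEE prediction
    and of the prediction residual against MTA.
    """
    if len(per_scan) < 4:
        raise InsufficientDataError(f"need >= 4 scans for correlations, got {len(per_scan)}")
    mta = np.array([s.mta for s in per_scan])
    si = np.array([s.si for s in per_scan])
    if mean_de is None:
        mean_de = float(np.mean([s.de for s in per_scan]))
    if mean_oer is None:
        mean_oer = float(np.mean([s.oer for s in per_scan]))
    spearman_pairs = {
        "MTA_vs_DE": np.array([s.de for s in per_scan]),
        "MTA_vs_OE": np.array([s.oe for s in per_scan]),
        "MTA_vs_OER": np.array([s.oer for s in per_scan]),
        "MTA_vs_SI": si,
    }
    out = {"spearman": [], "pearson": []}
    for name, col in spearman_pairs.items():
        rho, p = spearman(mta, col)
        out["spearman"].append((name, rho, p))

    pred = si_estimate(mean_de, mean_oer, mta)
    for name, a, b in (
        ("SI_vs_SIestimate", si, pred),
        ("residual_vs_MTA", si - pred, mta),
    ):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("Pearson correlation %s undefined (constant column)", name)
            out["pearson"].append((name, math.nan, math.nan))
        else:
            r, p = stats.pearsonr(a, b)
            out["pearson"].append((name, float(r), float(p)))
    return out


@dataclass(frozen=True)
class FittedModel:
    """One fitted SI-vs-MTA model with its fit diagnostics."""

    name: str
    k: int
    params: np.ndarray
    rss: float
    aicc: float
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False, compare=False)


class SimilarityBurdenModel:
    """Model of per-scan similarity as a function of lesion burden.

    Parameters
    ----------
    per_scan : sequence of ScanAgreement
        One agreement record per scan; all must have MTA > 0.

    Examples
    --------
    >>> fit = SimilarityBurdenModel(per_scan).fit()   # doctest: +SKIP
    >>> print(fit.summary())                          # doctest: +SKIP
    """

    def __init__(self, per_scan: Sequence[ScanAgreement]):
        max_k = max(MODEL_K.values())
        if len(per_scan) < max_k + 2:
            raise InsufficientDataError(
                f"need at least {max_k + 2} scans to fit and rank all models, got {len(per_scan)}"
            )
        if any(s.mta <= 0 for s in per_scan):
            raise DomainError("every scan must have MTA > 0")
        self.per_scan = list(per_scan)
        self.mta = np.array([s.mta for s in per_scan], float)
        self.si = np.array([s.si for s in per_scan], float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SimilarityBurdenModel":
        """Build from a DataFrame with (at least) columns MTA, SI, DE, OER."""
        for col in ("MTA", "SI", "DE", "OER"):
            if col not in df.columns:
                raise DomainError(f"missing required column {col!r}")
        scans = [
            ScanAgreement(
                scan_id=str(row.get("scan_id", i)),
                mta=float(row["MTA"]),
                de=float(row["DE"]),
                oe=float(row["OER"]) * float(row["MTA"]) if "OE" not in df.columns else float(row["OE"]),
                oer=float(row["OER"]),
                si=float(row["SI"]),
                ji=float(row["SI"]) / (2 - float(row["SI"])) if row["SI"] < 2 else 1.0,
                n_cr1=int(row.get("n_cr1", 0)),
                n_cr2=int(row.get("n_cr2", 0)),
                n_cr12=int(row.get("n_cr12", 0)),
            )
            for i, row in df.iterrows()
        ]
        return cls(scans)

    def fit(self) -> "StudyFit":
        """Fit all four models and assemble the results object."""
        n = len(self.per_scan)
        mta, si = self.mta, self.si
        mean_de = float(np.mean([s.de for s in self.per_scan]))
        mean_oer = float(np.mean([s.oer for s in self.per_scan]))

        models: dict[str, FittedModel] = {}

        def _add(name: str, params: np.ndarray, predict: Callable) -> None:
            resid = si - predict(mta)
            rss = float(resid @ resid)
            models[name] = FittedModel(
                name=name,
                k=MODEL_K[name],
                params=np.asarray(params, float),
                rss=rss,
                aicc=aicc(rss, n, MODEL_K[name]),
                predict=predict,
            )

        _add("mean", [si.mean()], lambda x, c=si.mean(): np.full_like(np.asarray(x, float), c))

        X1 = sm.add_constant(mta)
        ols1 = sm.OLS(si, X1).fit()
        _add("linear", ols1.params, lambda x, b=ols1.params: b[0] + b[1] * np.asarray(x, float))

        X2 = sm.add_constant(np.column_stack([mta, mta**2]))
        ols2 = sm.OLS(si, X2).fit()
        _add(
            "quadratic",
            ols2.params,
            lambda x, b=ols2.params: b[0] + b[1] * np.asarray(x, float) + b[2] * np.asarray(x, float) ** 2,
        )

        _add(
            "doee",
            [mean_de, mean_oer],
            lambda x, d=mean_de, o=mean_oer: si_estimate(d, o, x),
        )

        correlations = correlation_battery(self.per_scan, mean_de, mean_oer)
        return StudyFit(
            per_scan=self.per_scan,
            mean_de=mean_de,
            mean_oer=mean_oer,
            models=models,
            spearman=correlations["spearman"],
            pearson=correlations["pearson"],
        )


@dataclass
class StudyFit:
    """Results of a similarity-vs-burden study fit (see the module docstring)."""

    per_scan: list[ScanAgreement]
    mean_de: float
    mean_oer: float
    models: dict[str, FittedModel]
    spearman: list[tuple[str, float, float]]
    pearson: list[tuple[str, float, float]]

    @property
    def n_scans(self) -> int:
        return len(self.per_scan)

    @property
    def best_model(self) -> str:
        return min(self.models.values(), key=lambda m: m.aicc).name

    def relative_likelihoods(self) -> dict[str, float]:
        """Likelihood of each model relative to the AICc-best one."""
        names = list(self.models)
        rl = relative_likelihood([self.models[m].aicc for m in names])
        return dict(zip(names, rl.tolist()))

    def model_table(self) -> pd.DataFrame:
        rl = self.relative_likelihoods()
        return pd.DataFrame(
            [
                {
                    "model": m.name,
                    "k": m.k,
                    "params": np.round(m.params, 6).tolist(),
                    "RSS": m.rss,
                    "AICc": m.aicc,
                    "rel_likelihood": rl[m.name],
                }
                for m in self.models.values()
            ]
        ).set_index("model")

    def summary(self) -> str:
        """Human-readable study report."""
        lines = [
            "Similarity vs lesion burden — study fit",
            "=" * 55,
            f"scans: {self.n_scans}",
            f"meanDE:  {self.mean_de:10.1f} mm^2",
            f"meanOER: {self.mean_oer:10.4f}",
            f"best model by AICc: {self.best_model}",
            "",
            self.model_table().to_string(
                float_format=lambda v: f"{v:.4g}", columns=["k", "RSS", "AICc", "rel_likelihood"]
            ),
            "",
            "Spearman rank correlations:",
        ]
        for name, rho, p in self.spearman:
            lines.append(f"  {name:18s} rho = {rho:7.3f}   p = {p:.3g}")
        lines.append("Pearson correlations:")
        for name, r, p in self.pearson:
            lines.append(f"  {name:18s} r   = {r:7.3f}   p = {p:.3g}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> dict:
        """Study report as a JSON-serializable dict; optionally written."""
        rl = self.relative_likelihoods()
        doc = {
            "n_scans": self.n_scans,
            "meanDE": self.mean_de,
            "meanOER": self.mean_oer,
            "best_model": self.best_model,
            "per_scan": [
                {
                    "scan_id": s.scan_id,
                    "MTA": s.mta,
                    "DE": s.de,
                    "OE": s.oe,
                    "OER": s.oer,
                    "SI": s.si,
                    "JI": s.ji,
                    "n_cr1": s.n_cr1,
                    "n_cr2": s.n_cr2,
                    "n_cr12": s.n_cr12,
                }
                for s in self.per_scan
            ],
            "models": [
                {
                    "name": m.name,
                    "k": m.k,
                    "params": m.params.tolist(),
                    "RSS": m.rss,
                    "AICc": m.aicc,
                    "rel_likelihood": rl[m.name],
                }
                for m in self.models.values()
            ],
            "spearman": [
                {"pair": n_, "rho": r, "p": p} for n_, r, p in self.spearman
            ],
            "pearson": [{"pair": n_, "r": r, "p": p} for n_, r, p in self.pearson],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2, allow_nan=True))
        return doc


def fit_study(per_scan: Sequence[ScanAgreement]) -> StudyFit:
    """Convenience wrapper: ``SimilarityBurdenModel(per_scan).fit()``."""
    return SimilarityBurdenModel(per_scan).fit()
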