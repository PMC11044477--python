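"""Association of acoustic features with lobar imaging and spirometry.

Chest locations are mapped to lung lobes (anterior recordings to the
upper lobes, posterior to the lower lobes, right lateral to the right
middle lobe; the left lateral site has no middle-lobe counterpart and is
excluded from lobar models). Features are variance-stabilized — natural
log for E/I ratios, square root for crackle counts, log for airway
resistance and mid-expiratory flow — and each feature–endpoint pair is
fitted with a linear mixed-effects model: random intercepts for subject
and zone for the lobar comparisons, subject only for the
assessment-level spirometry comparisons. Estimation is REML with a Wald
test on the slope.

Interobserver agreement tooling (two-way absolute-agreement
average-measures ICC, Bland–Altman limits), Spearman interdependency of
imaging subscores and the per-family Bonferroni-adjusted significance
level complete the statistical surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_audio import ChestLocation

__all__ = [
    "LOCATION_TO_ZONE",
    "ZONES",
    "AssociationResult",
    "LobarAssociationModel",
    "map_location_to_zone",
    "transform_features",
    "fit_lobar_model",
    "fit_spirometry_model",
    "icc_average_measures",
    "bland_altman",
    "subscore_interdependency",
    "adjusted_alpha",
]

ZONES = ("RUL", "RML", "RLL", "LUL", "LLL")

LOCATION_TO_ZONE: dict[ChestLocation, str | None] = {
    ChestLocation.ANTERIOR_RIGHT: "RUL",
    ChestLocation.ANTERIOR_LEFT: "LUL",
    ChestLocation.POSTERIOR_RIGHT: "RLL",
    ChestLocation.POSTERIOR_LEFT: "LLL",
    ChestLocation.LATERAL_RIGHT: "RML",
    ChestLocation.LATERAL_LEFT: None,  # no left middle lobe
}

#: Endpoint-family sizes for the multiplicity adjustment: six CT score
#: columns, three functional-imaging columns, five spirometry columns.
FAMILY_ENDPOINTS = {"cfct": 6, "fri": 3, "spirometry": 5}


def map_location_to_zone(location: ChestLocation | str) -> str | None:
    """Lung lobe auscultated at a chest location (None: excluded)."""
    if isinstance(location, str):
        try:
            location = ChestLocation(location)
        except ValueError as exc:
            raise ValueError(f"unknown chest location {location!r}") from exc
    return LOCATION_TO_ZONE[location]


def adjusted_alpha(family: str, n_endpoints: int | None = None) -> float:
    """Bonferroni-style per-family significance level, 0.05 divided by
    the number of endpoints in the family."""
    if n_endpoints is None:
        try:
            n_endpoints = FAMILY_ENDPOINTS[family]
        except KeyError as exc:
            raise ValueError(
                f"unknown family {family!r}; give n_endpoints explicitly"
            ) from exc
    if n_endpoints < 1:
        raise ValueError("n_endpoints must be >= 1")
    return 0.05 / n_endpoints


_EI_COLUMNS = ("ei_100_200", "ei_200_400", "ei_400_800", "ei_800_1600")
_CRACKLE_COLUMNS = ("crackles_full", "crackles_insp", "crackles_exp")
_LOG_CLINICAL = ("iRaw", "MEF25_75", "MEF25")


def transform_features(
    table: pd.DataFrame, epsilon: float = 1e-3
) -> pd.DataFrame:
    """Variance-stabilizing transforms on a feature/clinical table.

    E/I ratios -> natural log (zeros floored at ``epsilon`` and flagged
    in a ``transform_flags`` column); crackle counts -> square root;
    airway resistance and mid/late expiratory flows -> natural log.
    Transformed values land in new ``log_*`` / ``sqrt_*`` columns.
    """
    out = table.copy()
    flags = pd.Series("", index=out.index, dtype=object)
    for col in _EI_COLUMNS:
        if col not in out:
            continue
        v = out[col].astype(float)
        if (v < 0).any():
            raise ValueError(f"negative values in {col}; cannot log-transform")
        floored = v < epsilon
        flags[floored & v.notna()] = (
            flags[floored & v.notna()] + f"{col}_floored;"
        )
        out[f"log_{col}"] = np.log(v.clip(lower=epsilon))
    for col in _CRACKLE_COLUMNS:
        if col not in out:
            continue
        v = out[col].astype(float)
        if (v < 0).any():
            raise ValueError(f"negative values in {col}; cannot sqrt-transform")
        out[f"sqrt_{col}"] = np.sqrt(v)
    for col in _LOG_CLINICAL:
        if col not in out:
            continue
        v = out[col].astype(float)
        if (v <= 0).any():
            raise ValueError(f"non-positive values in {col}; cannot log-transform")
        out[f"log_{col}"] = np.log(v)
    out["transform_flags"] = flags
    return out


@dataclass(frozen=True)
class AssociationResult:
    """One fitted feature-endpoint association."""

    outcome: str
    predictor: str
    slope: float
    stderr: float
    p_value: float
    direction: str  # "positive" | "negative" | "ns"
    n_obs: int
    alpha: float
    adjusted_alpha: float | None = None
    conf_int: tuple[float, float] | None = None
    flags: frozenset[str] = frozenset()

    def summary(self) -> str:
        arrow = {"positive": "↗", "negative": "↘", "ns": " "}[self.direction]
        lines = [
            f"Mixed-effects association: {self.outcome} ~ {self.predictor}",
            f"  n_obs          {self.n_obs}",
            f"  slope          {self.slope:+.4f} (SE {self.stderr:.4f})",
            f"  95% CI         [{self.conf_int[0]:+.4f}, {self.conf_int[1]:+.4f}]"
            if self.conf_int
            else "  95% CI         n/a",
            f"  p-value        {self.p_value:.4g} {arrow}",
            f"  alpha          {self.alpha:g}"
            + (f" (adjusted {self.adjusted_alpha:.4g})" if self.adjusted_alpha else ""),
        ]
        if self.flags:
            lines.append(f"  flags          {', '.join(sorted(self.flags))}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "slope": self.slope,
            "stderr": self.stderr,
            "p_value": self.p_value,
            "direction": self.direction,
            "n_obs": self.n_obs,
            "adjusted_alpha": self.adjusted_alpha,
            "flags": ";".join(sorted(self.flags)),
        }


class LobarAssociationModel:
    """Linear mixed-effects model of one acoustic outcome on one
    imaging/spirometry predictor.

    Parameters
    ----------
    data : DataFrame
        Long table with ``subject_id`` (and ``zone`` for the lobar
        structure) plus the outcome and predictor columns, already on
        their transformed scales.
    outcome, predictor : str
        Column names.
    random : {"crossed", "nested", "subject"}
        ``"crossed"`` (default): random intercepts for subject and for
        zone as crossed factors. ``"nested"``: zone intercepts nested
        within subject. ``"subject"``: subject intercept only (the
        spirometry variant).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        predictor: str,
        random: str = "crossed",
        alpha: float = 0.05,
        adjusted_alpha: float | None = None,
    ) -> None:
        if random not in ("crossed", "nested", "subject"):
            raise ValueError(f"unknown random-effects structure {random!r}")
        cols = ["subject_id", outcome, predictor] + (
            ["zone"] if random != "subject" else []
        )
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        self.data = data.dropna(subset=cols).copy()
        self.outcome = outcome
        self.predictor = predictor
        self.random = random
        self.alpha = alpha
        self.adjusted_alpha = adjusted_alpha
        if self.data["subject_id"].nunique() < 10:
            raise ValueError("at least 10 subjects required")

    def fit(self, reml: bool = True) -> AssociationResult:
        df = self.data
        formula = f"Q('{self.outcome}') ~ Q('{self.predictor}')"
        flags: set[str] = set()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                if self.random == "crossed":
                    df = df.assign(_one=1)
                    model = sm.MixedLM.from_formula(
                        formula,
                        groups="_one",
                        vc_formula={
                            "subject": "0 + C(subject_id)",
                            "zone": "0 + C(zone)",
                        },
                        data=df,
                    )
                elif self.random == "nested":
                    model = sm.MixedLM.from_formula(
                        formula,
                        groups="subject_id",
                        re_formula="1",
                        vc_formula={"zone": "0 + C(zone)"},
                        data=df,
                    )
                else:
                    model = sm.MixedLM.from_formula(
                        formula, groups="subject_id", data=df
                    )
                res = model.fit(reml=reml)
            except Exception as exc:  # singular / non-converged fit
                return AssociationResult(
                    outcome=self.outcome,
                    predictor=self.predictor,
                    slope=float("nan"),
                    stderr=float("nan"),
                    p_value=float("nan"),
                    direction="ns",
                    n_obs=len(df),
                    alpha=self.alpha,
                    adjusted_alpha=self.adjusted_alpha,
                    flags=frozenset({"fit_failed", type(exc).__name__}),
                )
            for w in caught:
                if "singular" in str(w.message).lower():
                    flags.add("singular_fit")
                elif "converge" in str(w.message).lower():
                    flags.add("convergence_warning")
        name = f"Q('{self.predictor}')"
        slope = float(res.params[name])
        stderr = float(res.bse[name])
        p = float(res.pvalues[name])
        ci = res.conf_int().loc[name]
        threshold = self.alpha
        direction = "ns"
        if np.isfinite(p) and p < threshold and "singular_fit" not in flags:
            direction = "positive" if slope > 0 else "negative"
        return AssociationResult(
            outcome=self.outcome,
            predictor=self.predictor,
            slope=slope,
            stderr=stderr,
            p_value=p,
            direction=direction,
            n_obs=len(df),
            alpha=self.alpha,
            adjusted_alpha=self.adjusted_alpha,
            conf_int=(float(ci[0]), float(ci[1])),
            flags=frozenset(flags),
        )


def fit_lobar_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    random: str = "crossed",
    alpha: float = 0.05,
    adjusted_alpha: float | None = None,
) -> AssociationResult:
    """Fit one lobar association (random intercepts for subject and zone)."""
    return LobarAssociationModel(
        data, outcome, predictor, random=random, alpha=alpha, adjusted_alpha=adjusted_alpha
    ).fit()


def fit_spirometry_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    alpha: float = 0.05,
    adjusted_alpha: float | None = None,
) -> AssociationResult:
    """Fit one assessment-level association (subject intercept only);
    expects one recording-averaged feature value per assessment."""
    return LobarAssociationModel(
        data, outcome, predictor, random="subject", alpha=alpha, adjusted_alpha=adjusted_alpha
    ).fit()


def icc_average_measures(
    scores_obs1: np.ndarray, scores_obs2: np.ndarray
) -> float:
    """Two-way absolute-agreement average-measures intraclass correlation.

    From the two-way ANOVA mean squares with n subjects and k=2 raters::

        ICC = (MS_rows - MS_error) /
              (MS_rows + (MS_cols - MS_error) / n)

    Raises when the between-subject variance is zero (ICC undefined).
    """
    a = np.asarray(scores_obs1, dtype=float)
    b = np.asarray(scores_obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D score vectors required")
    n = a.size
    if n < 5:
        raise ValueError("at least 5 paired scores required")
    y = np.column_stack([a, b])
    k = 2
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n))


def bland_altman(
    scores_obs1: np.ndarray, scores_obs2: np.ndarray
) -> tuple[float, float, float]:
    """Agreement summary: (bias, lower, upper) where bias is the mean
    difference and the limits of agreement are bias ± 1.96 SD of the
    differences."""
    a = np.asarray(scores_obs1, dtype=float)
    b = np.asarray(scores_obs2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D score vectors required")
    if a.size < 3:
        raise ValueError("at least 3 pairs required")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def subscore_interdependency(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among imaging subscores.

    Expects one row per subject (first assessment only). Returns a long
    DataFrame with columns score_a, score_b, rho, p_value, flag; a
    column whose values are all tied is flagged and given NaN rho.
    """
    cols = list(data.columns)
    rows = []
    for i, ca in enumerate(cols):
        for cb in cols[i + 1 :]:
            a = data[ca].astype(float)
            b = data[cb].astype(float)
            flag = ""
            if a.nunique() <= 1 or b.nunique() <= 1:
                rho, p = float("nan"), float("nan")
                flag = "constant_column"
            else:
                rho, p = stats.spearmanr(a, b)
            rows.append(
                {"score_a": ca, "score_b": cb, "rho": rho, "p_value": p, "flag": flag}
            )
    return pd.DataFrame(rows)
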