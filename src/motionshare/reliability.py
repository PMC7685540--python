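"""Intra-/inter-investigator repeatability statistics for biomarker readings.

Implements the two-way random-effects ANOVA for a complete subjects x raters
matrix, single-measures intraclass correlation (absolute agreement by default,
consistency as an option) with the F-based 95% confidence interval, the
standard error of measurement (SEM) as the root error variance, and the
minimal difference MD = SEM * 1.96 * sqrt(2), together with the qualitative
reliability bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObservationMatrix",
    "AnovaTable",
    "RepeatabilityResult",
    "two_way_anova",
    "icc_two_way_random_single",
    "sem_from_anova",
    "minimal_difference",
    "categorize_icc",
    "repeatability_report",
]

MD_FACTOR = 1.96 * np.sqrt(2.0)

#: Qualitative ICC bands: (upper edge inclusive, label).
ICC_BANDS = (
    (0.40, "slight"),
    (0.60, "fair"),
    (0.80, "moderate"),
    (1.00, "substantial"),
)


@dataclass
class ObservationMatrix:
    """Complete n_subjects x k_raters matrix of one biomarker's readings."""

    values: np.ndarray
    subject_ids: list[str] | None = None
    rater_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x raters matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters/occasions")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not supported (complete design required)")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i + 1:02d}" for i in range(n)]
        if self.rater_ids is None:
            self.rater_ids = [f"R{j + 1}" for j in range(k)]
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str = "value") -> "ObservationMatrix":
        """Build from a long-format frame with columns subject, rater, value."""
        wide = df.pivot(index="subject", columns="rater", values=value_col)
        if wide.isna().any().any():
            raise ValueError("long-format input has missing subject/rater cells")
        return cls(
            values=wide.to_numpy(),
            subject_ids=[str(s) for s in wide.index],
            rater_ids=[str(r) for r in wide.columns],
        )


@dataclass
class AnovaTable:
    """Mean squares of the two-way random-effects ANOVA (no replication)."""

    ms_subjects: float
    ms_raters: float
    ms_error: float
    df_subjects: int
    df_raters: int
    df_error: int
    grand_mean: float
    pooled_sd: float  # SD of all n*k readings about the grand mean (sample form)
    n_subjects: int
    n_raters: int


@dataclass
class RepeatabilityResult:
    icc: float
    ci95: tuple[float, float]
    sem: float
    md: float
    category: str | None
    anova: AnovaTable
    icc_type: str = "agreement"
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": None if np.isnan(self.icc) else float(self.icc),
            "ci95": [
                None if np.isnan(v) else float(v) for v in self.ci95
            ],
            "sem": float(self.sem),
            "md": float(self.md),
            "category": self.category,
            "icc_type": self.icc_type,
            "undefined": self.undefined,
            "anova": {
                "ms_subjects": self.anova.ms_subjects,
                "ms_raters": self.anova.ms_raters,
                "ms_error": self.anova.ms_error,
                "pooled_sd": self.anova.pooled_sd,
                "grand_mean": self.anova.grand_mean,
            },
        }


def two_way_anova(m: ObservationMatrix) -> AnovaTable:
    """Mean squares for subjects, raters and residual of a complete matrix."""
    y = m.values
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    # residual computed directly (not by subtraction) to avoid cancellation
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    df_r, df_c, df_e = n - 1, k - 1, (n - 1) * (k - 1)
    return AnovaTable(
        ms_subjects=ss_rows / df_r,
        ms_raters=ss_cols / df_c,
        ms_error=ss_err / df_e,
        df_subjects=df_r,
        df_raters=df_c,
        df_error=df_e,
        grand_mean=float(grand),
        pooled_sd=float(np.sqrt(ss_total / (n * k - 1))) if n * k > 1 else 0.0,
        n_subjects=n,
        n_raters=k,
    )


def _agreement_ci(icc: float, anova: AnovaTable, alpha: float) -> tuple[float, float]:
    """F-based confidence interval for single-measures absolute-agreement ICC."""
    n, k = anova.n_subjects, anova.n_raters
    msr, msc, mse = anova.ms_subjects, anova.ms_raters, anova.ms_error
    if mse <= 0 and msc <= 0:
        return (icc, icc)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return (icc, icc)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    if den <= 0:
        return (icc, icc)
    v = num / den
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (msr - f_l * mse)) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_u * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return (float(lower), float(upper))


def _consistency_ci(anova: AnovaTable, alpha: float) -> tuple[float, float]:
    """Exact F interval for single-measures consistency ICC."""
    n, k = anova.n_subjects, anova.n_raters
    msr, mse = anova.ms_subjects, anova.ms_error
    if mse <= 0:
        return (1.0, 1.0)
    fobs = msr / mse
    df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
    fl = fobs / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    fu = fobs * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
    lower = (fl - 1.0) / (fl + k - 1.0)
    upper = (fu - 1.0) / (fu + k - 1.0)
    return (float(lower), float(upper))


def icc_two_way_random_single(
    m: ObservationMatrix,
    form: str = "agreement",
    alpha: float = 0.05,
) -> RepeatabilityResult:
    """Single-measures ICC under the two-way random-effects model.

    ``form="agreement"`` (default) is ICC(2,1) absolute agreement:
    ``(MS_S - MS_E) / (MS_S + (k-1) MS_E + (k/n)(MS_R - MS_E))``.
    ``form="consistency"`` drops the rater-variance term from the denominator.
    A constant matrix yields an undefined ICC (NaN, flagged), not an error.
    The returned SEM/MD use the root error variance (see
    :func:`sem_from_anova` for the sd_icc alternative).
    """
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    anova = two_way_anova(m)
    n, k = anova.n_subjects, anova.n_raters
    msr, msc, mse = anova.ms_subjects, anova.ms_raters, anova.ms_error
    if form == "agreement":
        denom = msr + (k - 1.0) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1.0) * mse
    degenerate = anova.pooled_sd <= 1e-12 * max(1.0, abs(anova.grand_mean))
    if denom <= 0 or degenerate:
        sem = sem_from_anova(anova)
        return RepeatabilityResult(
            icc=float("nan"),
            ci95=(float("nan"), float("nan")),
            sem=sem,
            md=minimal_difference(sem),
            category=None,
            anova=anova,
            icc_type=form,
            undefined=True,
        )
    icc = float((msr - mse) / denom)
    if form == "agreement":
        ci = _agreement_ci(icc, anova, alpha)
    else:
        ci = _consistency_ci(anova, alpha)
    sem = sem_from_anova(anova)
    return RepeatabilityResult(
        icc=icc,
        ci95=ci,
        sem=sem,
        md=minimal_difference(sem),
        category=categorize_icc(icc),
        anova=anova,
        icc_type=form,
    )


def sem_from_anova(
    anova: AnovaTable, method: str = "anova", icc: float | None = None
) -> float:
    """Standard error of measurement.

    ``method="anova"`` (default): root of the ANOVA error variance,
    SEM = sqrt(MS_E).  ``method="sd_icc"``: SEM = pooled_sd * sqrt(1 - ICC),
    using the SD of all readings about the grand mean.
    """
    if anova.ms_error < 0:
        raise ValueError("negative error mean square")
    if method == "anova":
        return float(np.sqrt(anova.ms_error))
    if method == "sd_icc":
        if icc is None:
            raise ValueError("method 'sd_icc' requires an ICC value")
        if icc > 1:
            raise ValueError("ICC > 1 is invalid for SEM computation")
        return float(anova.pooled_sd * np.sqrt(1.0 - icc))
    raise ValueError(f"unknown SEM method {method!r}")


def minimal_difference(sem: float) -> float:
    """MD = SEM * 1.96 * sqrt(2): the smallest change exceeding measurement
    error with 95% confidence."""
    if sem < 0:
        raise ValueError("sem must be >= 0")
    return float(sem * MD_FACTOR)


def categorize_icc(icc: float) -> str | None:
    """Qualitative band for an ICC: slight (0.11-0.40), fair (0.41-0.60),
    moderate (0.61-0.80), substantial (0.81-1.00); below 0.11 -> below-slight.

    Upper edges are inclusive.  NaN returns None.
    """
    if np.isnan(icc):
        return None
    if icc > 1.0:
        raise ValueError("ICC above 1 cannot be categorised")
    if icc < 0.11:
        return "below-slight"
    for edge, label in ICC_BANDS:
        if icc <= edge + 1e-12:
            return label
    return "substantial"


def icc_sem_roundtrip(sem: float, pooled_sd: float) -> float:
    """Recover the ICC implied by SEM = SD * sqrt(1 - ICC): 1 - (SEM/SD)^2."""
    if pooled_sd <= 0:
        raise ValueError("pooled_sd must be > 0")
    return float(1.0 - (sem / pooled_sd) ** 2)


def sem_percent_of_mean(sem: float, group_mean: float) -> float:
    """SEM expressed as a percentage of the group mean."""
    if group_mean == 0:
        raise ValueError("group mean is zero")
    return float(100.0 * sem / abs(group_mean))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _reading_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Group mean/SD per biomarker and rater (descriptive table layout)."""
    return (
        df.groupby(["biomarker", "rater"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )


def repeatability_report(
    readings: pd.DataFrame,
    pairs: dict[str, tuple[str, str]] | None = None,
    form: str = "agreement",
    outdir=None,
) -> dict:
    """Full repeatability analysis of long-format readings.

    ``readings`` needs columns subject, rater, biomarker, value.  ``pairs``
    maps a pairing name (e.g. ``"intra"``) to the two rater/occasion labels to
    compare; defaults to all rater pairs.  Returns a dict with the descriptive
    summary, one :class:`RepeatabilityResult` per (biomarker, pairing), and
    SEM-as-percent-of-mean.  When ``outdir`` is given, writes CSV/Markdown
    tables and identity-line scatterplots there.
    """
    required = {"subject", "rater", "biomarker", "value"}
    if not required.issubset(readings.columns):
        raise ValueError(f"readings must have columns {sorted(required)}")
    raters = sorted(readings["rater"].unique())
    if pairs is None:
        pairs = {
            f"{a}-vs-{b}": (a, b)
            for i, a in enumerate(raters)
            for b in raters[i + 1 :]
        }
    summary = _reading_summary(readings)
    results: dict[tuple[str, str], RepeatabilityResult] = {}
    rows = []
    for biom in sorted(readings["biomarker"].unique()):
        sub = readings[readings["biomarker"] == biom]
        for name, (ra, rb) in pairs.items():
            pair_df = sub[sub["rater"].isin([ra, rb])]
            subj_a = set(pair_df[pair_df["rater"] == ra]["subject"])
            subj_b = set(pair_df[pair_df["rater"] == rb]["subject"])
            if subj_a != subj_b:
                raise ValueError(
                    f"mismatched subject sets for pairing {name!r} on {biom!r}"
                )
            matrix = ObservationMatrix.from_long(pair_df)
            res = icc_two_way_random_single(matrix, form=form)
            results[(biom, name)] = res
            gm = res.anova.grand_mean
            rows.append(
                {
                    "biomarker": biom,
                    "pairing": name,
                    "icc": round(res.icc, 2) if not np.isnan(res.icc) else None,
                    "ci_lower": round(res.ci95[0], 2) if not np.isnan(res.ci95[0]) else None,
                    "ci_upper": round(res.ci95[1], 2) if not np.isnan(res.ci95[1]) else None,
                    "category": res.category,
                    "sem": round(res.sem, 3),
                    "sem_pct_mean": round(sem_percent_of_mean(res.sem, gm))
                    if gm != 0
                    else None,
                    "md": round(res.md, 3),
                }
            )
    table = pd.DataFrame(rows)
    out = {"summary": summary, "results": results, "table": table}
    if outdir is not None:
        _write_report(readings, summary, table, results, pairs, outdir)
    return out


def _write_report(readings, summary, table, results, pairs, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "group_summary.csv", index=False)
    table.to_csv(outdir / "repeatability.csv", index=False)
    lines = ["# Repeatability report", "", "## Group means and SDs", ""]
    lines.append(summary.to_markdown(index=False))
    lines += ["", "## ICC / SEM / MD", "", table.to_markdown(index=False), ""]
    (outdir / "report.md").write_text("\n".join(lines))
    for (biom, name), res in results.items():
        ra, rb = pairs[name]
        sub = readings[readings["biomarker"] == biom]
        wide = sub[sub["rater"].isin([ra, rb])].pivot(
            index="subject", columns="rater", values="value"
        )
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(wide[ra], wide[rb], s=18, color="tab:blue")
        lim = [
            min(wide.min().min(), 0),
            wide.max().max() * 1.05,
        ]
        ax.plot(lim, lim, "k--", lw=1, label="identity")
        ax.set_xlim(lim)
        ax.set_ylim(lim)
        ax.set_xlabel(f"{biom} ({ra})")
        ax.set_ylabel(f"{biom} ({rb})")
        icc_txt = "undefined" if np.isnan(res.icc) else f"{res.icc:.2f}"
        ax.set_title(f"{biom} {name}: ICC {icc_txt}")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"scatter_{biom}_{name}.png", dpi=100)
        plt.close(fig)
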