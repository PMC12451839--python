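"""Residual-based longitudinal outlier detection.

Each region is screened by fitting the adjustment model — a penalized
smooth of age, a sex main effect, an age-by-sex difference smooth, and a
per-subject random intercept — and flagging statistical outliers among the
residuals taken against the *population-level* (fixed-effect) prediction.
Using the fixed-effect residual keeps subject offsets visible: a shifted
subject's residuals would otherwise be absorbed into their random-intercept
estimate and escape the between-subject rule.

Two rules, both at a configurable threshold (default 2 SD):

* between-subject — subjects whose mean residual lies >= threshold SDs from
  the across-subject mean of subject-mean residuals (SD = across-subject SD
  of the subject means);
* within-subject — observations >= threshold SDs from the subject's own
  mean residual, standardized by the pooled within-subject residual SD with
  a finite-sample factor sqrt(1 - 1/n_i) so the Gaussian null false-flag
  rate is the nominal 2*Phi(-threshold) (~4.6% at 2 SD).

Flagged records are marked for review, never silently removed; an explicit
``exclude`` step drops them to emulate a human-adjudicated final decision.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_model import LongitudinalDataset
from .gamm_engine import SmoothSpec, fit_gamm

__all__ = ["OutlierReport", "detect_outliers", "exclude_flagged"]


@dataclasses.dataclass
class OutlierReport:
    """Flags from both rules plus the thresholds and counts used."""

    region: str
    threshold_sd: float
    flags: pd.DataFrame   # subject_id, wave, region, kind, z
    n_obs: int
    n_subjects: int
    notes: list

    @property
    def between_subject(self) -> pd.DataFrame:
        return self.flags[self.flags["kind"] == "between_subject"]

    @property
    def within_subject(self) -> pd.DataFrame:
        return self.flags[self.flags["kind"] == "within_subject"]

    def counts(self) -> dict:
        return {
            "between_subject": int(len(self.between_subject)),
            "within_subject": int(len(self.within_subject)),
        }


def detect_outliers(dataset: LongitudinalDataset, region: str,
                    threshold_sd: float = 2.0,
                    spec: SmoothSpec | None = None) -> OutlierReport:
    """Flag residual outliers for one region (records marked, not removed)."""
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    spec = spec or SmoothSpec()
    fit = fit_gamm(dataset, region, spec)
    df = fit.frame.copy()
    df["resid"] = fit.fixed_residuals
    notes = []
    flags = []

    # between-subject rule on subject-mean residuals
    yscale = float(np.abs(df["volume"]).mean()) + 1e-300
    subj_mean = df.groupby("subject_id")["resid"].mean()
    mu, sd = subj_mean.mean(), subj_mean.std(ddof=1)
    if sd > 1e-10 * yscale:
        z_between = (subj_mean - mu) / sd
        for sid, z in z_between.items():
            if abs(z) >= threshold_sd:
                flags.append((sid, pd.NA, region, "between_subject", float(z)))
    else:
        notes.append("between-subject rule skipped: zero spread")

    # within-subject rule on deviations from each subject's own mean
    df["dev"] = df["resid"] - df.groupby("subject_id")["resid"].transform("mean")
    n_i = df.groupby("subject_id")["resid"].transform("count")
    multi = n_i > 1
    if (~multi).any():
        skipped = df.loc[~multi, "subject_id"].unique().tolist()
        notes.append(
            f"within-subject rule skipped for single-observation "
            f"subject(s): {skipped}")
    if multi.any():
        dev = df.loc[multi, "dev"].to_numpy()
        nn = n_i[multi].to_numpy(float)
        # pooled within-subject SD; deviations carry (1 - 1/n_i) of sigma^2
        denom = float(np.sum(nn > 0)) - df.loc[multi, "subject_id"].nunique()
        pooled_var = float(np.sum(dev * dev)) / max(denom, 1.0)
        pooled_sd = np.sqrt(pooled_var)
        if pooled_sd > 1e-10 * yscale:
            z = dev / (pooled_sd * np.sqrt(1.0 - 1.0 / nn))
            hit = np.abs(z) >= threshold_sd
            sub = df.loc[multi]
            for (_, row), zi, h in zip(sub.iterrows(), z, hit):
                if h:
                    flags.append((row["subject_id"], int(row["wave"]),
                                  region, "within_subject", float(zi)))

    flag_df = pd.DataFrame(
        flags, columns=["subject_id", "wave", "region", "kind", "z"])
    return OutlierReport(region=region, threshold_sd=threshold_sd,
                         flags=flag_df, n_obs=len(df),
                         n_subjects=df["subject_id"].nunique(), notes=notes)


def exclude_flagged(dataset: LongitudinalDataset, report: OutlierReport
                    ) -> LongitudinalDataset:
    """Drop flagged records: every observation of a between-subject-flagged
    subject in that region, and each within-subject-flagged (subject, wave).

    This automates what was a human visual-inspection decision in practice;
    use it deliberately.
    """
    df = dataset.frame
    drop = pd.Series(False, index=df.index)
    between = set(report.between_subject["subject_id"])
    if between:
        drop |= (df["region"] == report.region) & \
            df["subject_id"].isin(between)
    for _, row in report.within_subject.iterrows():
        drop |= ((df["region"] == report.region)
                 & (df["subject_id"] == row["subject_id"])
                 & (df["wave"] == row["wave"]))
    out = dataset.copy()
    out.frame = df.loc[~drop].reset_index(drop=True)
    return out
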