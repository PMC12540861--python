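"""Longitudinal and cohort-level analysis of ctDNA monitoring courses.

Covers four jobs that sit downstream of per-sample quantification:

* retrospective germline flagging — a panel SNV whose consensus VAF stays
  high and stable across the whole treatment course behaves like an
  inherited variant, not ctDNA, and is removed from MTM totals;
* tumor volume from radiology diameters via the ellipsoid formula
  V = (pi/6)·d1·d2·d3, with the field's standard imputation when one or two
  diameters are missing;
* Spearman rank correlations (exact permutation p-values at small n);
* cohort summary tables (pre-treatment cfDNA/ctDNA by disease extent, QC
  exclusions, germline flags, panel sizes) and per-patient trajectory tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ctdna_quant import (
    POSITIVITY_MTM_PER_ML,
    QC_MIN_CONSENSUS,
    SampleQuantification,
    classify_sample,
)

GERMLINE_MIN_SAMPLES = 4
GERMLINE_VAF_FLOOR = 0.20
GERMLINE_MAX_CV = 0.25


@dataclass
class TumorMeasurement:
    """Orthogonal tumor diameters from one imaging time point.

    Diameters share one length unit (typically cm); the derived volume is in
    that unit cubed.  Any of the three may be missing (None).
    """

    day: float
    d1: float | None = None
    d2: float | None = None
    d3: float | None = None

    @property
    def volume(self) -> float:
        return ellipsoid_volume(self)


@dataclass
class GermlineFlag:
    snv_id: str
    flagged: bool
    indeterminate: bool
    vaf_series: list[float]
    mean_vaf: float | None = None
    cv: float | None = None


@dataclass
class CorrelationResult:
    n: int
    spearman_r: float
    p_value: float
    undefined: bool = False


@dataclass
class PatientCourse:
    """One patient's monitoring course.

    ``sample_sheet`` holds the per-sample metadata (day, plasma volume,
    cfDNA ng/mL, treatment phase); ``quantifications`` are attached once the
    sequencing pipeline has run.  ``relapse_days`` lists days of clinically
    confirmed relapse/progression (possibly empty).
    """

    patient_id: str
    sample_sheet: pd.DataFrame
    measurements: list[TumorMeasurement] = field(default_factory=list)
    treatments: list[tuple[float, float, str]] = field(default_factory=list)
    relapse_days: list[float] = field(default_factory=list)
    metastatic: bool = False
    quantifications: list[SampleQuantification] = field(default_factory=list)
    germline_flags: list[GermlineFlag] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = list(self.sample_sheet["day"])
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample days must be strictly increasing")

    def attach_quantifications(self, quants: list[SampleQuantification]) -> None:
        days = [q.day for q in quants]
        if len(set(days)) != len(days):
            raise ValueError("at most one quantification per day")
        self.quantifications = sorted(quants, key=lambda q: q.day)

    @property
    def passing(self) -> list[SampleQuantification]:
        return [q for q in self.quantifications if not q.excluded]

    def pretreatment(self) -> SampleQuantification | None:
        """Earliest non-excluded sample (the baseline draw)."""
        return self.passing[0] if self.passing else None

    def pretreatment_cfdna(self) -> float | None:
        q = self.pretreatment()
        if q is None:
            return None
        row = self.sample_sheet.loc[self.sample_sheet["day"] == q.day]
        return float(row["cfdna_ng_ml"].iloc[0]) if len(row) else None


# ---------------------------------------------------------------------------
# germline flagging


def flag_germline(
    vaf_series: list[float],
    snv_id: str = "",
    min_samples: int = GERMLINE_MIN_SAMPLES,
    vaf_floor: float = GERMLINE_VAF_FLOOR,
    max_cv: float = GERMLINE_MAX_CV,
) -> GermlineFlag:
    """Flag an SNV as germline from its consensus-VAF series.

    A germline heterozygous variant sits near 50% allele fraction in plasma
    regardless of tumor burden, so its VAF series across passing samples is
    high and flat while true somatic targets track treatment response.  The
    rule: at least ``min_samples`` samples, VAF >= ``vaf_floor`` in every
    sample, and coefficient of variation (sample SD / mean) <= ``max_cv``.
    Shorter series are indeterminate, never flagged.
    """
    series = [float(v) for v in vaf_series]
    if len(series) < min_samples:
        return GermlineFlag(
            snv_id=snv_id, flagged=False, indeterminate=True, vaf_series=series
        )
    mean = float(np.mean(series))
    sd = float(np.std(series, ddof=1))
    cv = sd / mean if mean > 0 else math.inf
    flagged = all(v >= vaf_floor for v in series) and cv <= max_cv
    return GermlineFlag(
        snv_id=snv_id,
        flagged=flagged,
        indeterminate=False,
        vaf_series=series,
        mean_vaf=mean,
        cv=cv,
    )


def flag_and_requantify(
    quantifications: list[SampleQuantification],
    min_samples: int = GERMLINE_MIN_SAMPLES,
    vaf_floor: float = GERMLINE_VAF_FLOOR,
    max_cv: float = GERMLINE_MAX_CV,
    qc_min_consensus: int = QC_MIN_CONSENSUS,
    positivity_mtm_per_ml: float = POSITIVITY_MTM_PER_ML,
) -> tuple[list[GermlineFlag], list[SampleQuantification]]:
    """Flag germline SNVs across a patient's course and re-quantify.

    VAF series are drawn only from non-excluded samples in which the target
    had non-zero consensus depth.  Flagged targets are removed from every
    sample's counts and each sample is re-classified from the remaining
    assays (so MTM/mL can only decrease).
    """
    passing = [q for q in quantifications if not q.excluded]
    target_ids: list[str] = []
    for q in quantifications:
        for tid in q.per_target:
            if tid not in target_ids:
                target_ids.append(tid)
    flags = []
    for tid in target_ids:
        series = []
        for q in passing:
            cc = q.per_target.get(tid)
            if cc is not None and cc.consensus_vaf is not None:
                series.append(cc.consensus_vaf)
        flags.append(
            flag_germline(
                series,
                snv_id=tid,
                min_samples=min_samples,
                vaf_floor=vaf_floor,
                max_cv=max_cv,
            )
        )
    flagged_ids = {f.snv_id for f in flags if f.flagged}
    if not flagged_ids:
        return flags, list(quantifications)
    corrected = []
    for q in quantifications:
        kept = {tid: cc for tid, cc in q.per_target.items() if tid not in flagged_ids}
        corrected.append(
            classify_sample(
                kept,
                plasma_volume_ml=q.plasma_volume_ml,
                qc_min_consensus=qc_min_consensus,
                positivity_mtm_per_ml=positivity_mtm_per_ml,
                patient_id=q.patient_id,
                day=q.day,
            )
        )
    return flags, corrected


# ---------------------------------------------------------------------------
# tumor volume


def ellipsoid_volume(m: TumorMeasurement | None = None, d1=None, d2=None, d3=None) -> float:
    """Tumor volume from up to three orthogonal diameters.

    V = (pi/6)·d1·d2·d3.  With two diameters known, the third is imputed as
    their mean; with one known, a spherical tumor is assumed.  All-missing or
    negative diameters raise ``ValueError``.
    """
    if m is not None:
        d1, d2, d3 = m.d1, m.d2, m.d3
    ds = [d for d in (d1, d2, d3) if d is not None]
    if not ds:
        raise ValueError("at least one diameter is required")
    if any(d < 0 for d in ds):
        raise ValueError("diameters must be non-negative")
    if len(ds) == 1:
        ds = ds * 3
    elif len(ds) == 2:
        ds = ds + [sum(ds) / 2]
    return math.pi / 6 * ds[0] * ds[1] * ds[2]


# ---------------------------------------------------------------------------
# correlation


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's r (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry_c = ry - ry.mean()
    denom = ry_c.std() * n
    perms = np.array(list(itertools.permutations(range(n))))
    r_all = ry_c[perms] @ rx / denom
    hits = np.abs(r_all) >= abs(r_obs) - 1e-12
    return float(hits.mean())


def spearman_corr(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    The two-sided p-value is an exact permutation enumeration for
    n <= ``exact_max_n`` and the usual t approximation otherwise.  Constant
    series make r undefined; the result is returned with ``undefined=True``
    and NaN statistics rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(n=n, spearman_r=math.nan, p_value=math.nan, undefined=True)
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, r)
    else:
        p = float(res.pvalue)
    return CorrelationResult(n=n, spearman_r=r, p_value=p)


# ---------------------------------------------------------------------------
# cohort summary and trajectories


def _median_range(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "n": len(arr),
        "median": float(np.median(arr)) if len(arr) else math.nan,
        "min": float(arr.min()) if len(arr) else math.nan,
        "max": float(arr.max()) if len(arr) else math.nan,
    }


def summarize_cohort(courses: list[PatientCourse]) -> dict:
    """Cohort-level summary table.

    Pre-treatment cfDNA (ng/mL) and ctDNA (MTM/mL) median/range split by
    disease extent (metastatic vs localized), QC-excluded sample counts,
    flagged germline SNV counts, and per-patient panel SNV counts.
    Percentages are on the 0-100 scale.
    """
    if not courses:
        raise ValueError("need at least one course")
    groups = {"metastatic": [], "localized": []}
    for c in courses:
        groups["metastatic" if c.metastatic else "localized"].append(c)
    pretx = {}
    for name, members in groups.items():
        cf = [c.pretreatment_cfdna() for c in members]
        ct = [
            c.pretreatment().mtm_per_ml for c in members if c.pretreatment() is not None
        ]
        pretx[name] = {
            "cfdna_ng_ml": _median_range([v for v in cf if v is not None]),
            "ctdna_mtm_per_ml": _median_range(ct),
        }
    n_samples = sum(len(c.quantifications) for c in courses)
    n_excluded = sum(1 for c in courses for q in c.quantifications if q.excluded)
    panel_sizes = []
    n_panel_snvs = 0
    n_flagged = 0
    for c in courses:
        tids = set()
        for q in c.quantifications:
            tids.update(q.per_target)
        # flagged germline targets were removed from per_target on
        # re-quantification but still count toward the designed panel
        tids.update(f.snv_id for f in c.germline_flags)
        panel_sizes.append(len(tids))
        n_panel_snvs += len(tids)
        n_flagged += sum(1 for f in c.germline_flags if f.flagged)
    return {
        "n_patients": len(courses),
        "pretreatment": pretx,
        "samples": {
            "n_total": n_samples,
            "n_excluded": n_excluded,
            "pct_excluded": 100.0 * n_excluded / n_samples if n_samples else math.nan,
        },
        "germline": {
            "n_panel_snvs": n_panel_snvs,
            "n_flagged": n_flagged,
            "pct_flagged": 100.0 * n_flagged / n_panel_snvs if n_panel_snvs else math.nan,
        },
        "panel_snvs_per_patient": {
            "mean": float(np.mean(panel_sizes)) if panel_sizes else math.nan,
            "min": int(min(panel_sizes)) if panel_sizes else 0,
            "max": int(max(panel_sizes)) if panel_sizes else 0,
        },
    }


def build_trajectory(course: PatientCourse) -> dict:
    """Aligned per-patient series for tabulation or plotting.

    Returns a dict with a ``samples`` DataFrame (day, MTM/mL, status and one
    MTM column per panel SNV; QC-excluded samples are omitted), a ``volumes``
    DataFrame (day, volume), the treatment annotations and relapse days.
    Column and row order are deterministic.
    """
    target_ids: list[str] = []
    for q in course.quantifications:
        for tid in sorted(q.per_target):
            if tid not in target_ids:
                target_ids.append(tid)
    rows = []
    for q in course.quantifications:
        if q.excluded:
            continue
        row = {
            "day": q.day,
            "mtm_per_ml": q.mtm_per_ml,
            "mtm_total": q.mtm_total,
            "est_molecules": q.est_molecules,
            "status": q.status,
            "trace": q.status == "trace",
        }
        for tid in target_ids:
            cc = q.per_target.get(tid)
            row[f"mtm_{tid}"] = cc.mutant_consensus if cc is not None else 0
        rows.append(row)
    samples = pd.DataFrame(rows)
    volumes = pd.DataFrame(
        [{"day": m.day, "volume": m.volume} for m in course.measurements]
    )
    return {
        "patient_id": course.patient_id,
        "samples": samples,
        "volumes": volumes,
        "treatments": list(course.treatments),
        "relapse_days": list(course.relapse_days),
        "target_ids": target_ids,
    }


def plot_trajectory(course: PatientCourse, path=None):
    """Static three-panel trajectory plot (MTM/mL, tumor volume, per-SNV MTM)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = build_trajectory(course)
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    s = traj["samples"]
    if len(s):
        axes[0].plot(s["day"], s["mtm_per_ml"], "-o", color="black")
        trace = s[s["trace"]]
        axes[0].plot(trace["day"], trace["mtm_per_ml"], "o", mfc="white", mec="black")
    axes[0].set_ylabel("ctDNA (MTM/mL)")
    axes[0].set_yscale("symlog", linthresh=1.0)
    v = traj["volumes"]
    if len(v):
        axes[1].plot(v["day"], v["volume"], "-s", color="tab:blue")
    axes[1].set_ylabel("tumor volume")
    for tid in traj["target_ids"]:
        axes[2].plot(s["day"], s[f"mtm_{tid}"], "-", alpha=0.6, label=tid)
    axes[2].set_ylabel("MTM per SNV")
    axes[2].set_xlabel("day")
    for d in traj["relapse_days"]:
        for ax in axes:
            ax.axvline(d, color="red", ls="--", alpha=0.5)
    fig.suptitle(course.patient_id)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
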