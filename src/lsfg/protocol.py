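"""Five-stage carotid occlusion-reperfusion protocol analysis.

One *session* is one eye taken through BASELINE, ECAO (external carotid
artery occlusion), REPERFUSE1, ICAO (internal carotid artery occlusion) and
REPERFUSE2, with nominally ten LSFG recordings per stage.  This module
aggregates recordings into per-stage region metrics, applies the reperfusion
gate (flow must return to within +/-20 percent of baseline before the second
occlusion is analysed), and produces the cohort statistics: per-stage group
summaries (mean, sd, sem), paired t-tests of each stage against baseline,
normal-pair laterality standard ranges, occlusion laterality indices, and
inter-eye regressions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .datatypes import (Eye, MBRFrameStack, PROTOCOL_ORDER, ROI, ROILabel,
                        StageLabel, full_image_roi)
from .errors import CompleteOcclusion, ValidationError
from .io import temporal_mean
from .metrics import (DEFAULT_THRESHOLD, LateralityResult, Parameter,
                      RegionMetrics, StageBoundaries, StandardRange,
                      classify_perfusion_stage, compute_region_metrics,
                      compute_vpe, flag_abnormal, laterality_index_normal,
                      laterality_index_occlusion, perfusion_index,
                      segment_by_threshold, standard_range)
from .waveform import pulse_metrics, roi_timeseries

_LI_PARAMETERS = (Parameter.MV, Parameter.MT, Parameter.MA, Parameter.MV_MT,
                  Parameter.ARBS)
_REGRESSION_PARAMETERS = (Parameter.MV, Parameter.MT, Parameter.MA,
                          Parameter.MV_MT)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the protocol analysis.

    ``pooling`` selects the unit of the vessel-ROI cohort statistics:
    ``"vessel"`` pools all vessel ROIs across eyes (matching a 56-vessels-
    from-16-eyes design), ``"eye"`` averages each eye's vessels first.
    """

    segmentation_threshold: float = DEFAULT_THRESHOLD
    stage_boundaries: StageBoundaries = field(default_factory=StageBoundaries)
    pooling: str = "vessel"
    gate_parameter: Parameter = Parameter.MA
    gate_tolerance: float = 0.20
    alpha: float = 0.05
    strong_alpha: float = 0.001
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.pooling not in ("vessel", "eye"):
            raise ValidationError(f"pooling must be 'vessel' or 'eye', "
                                  f"got {self.pooling!r}")


@dataclass
class ProtocolSession:
    """One eye's recordings across the protocol stages, with its ROIs."""

    animal_id: str
    eye: Eye
    recordings: Mapping[StageLabel, Sequence[MBRFrameStack]]
    rois: Sequence[ROI]
    reperfusion_ok: Optional[bool] = None

    def __post_init__(self) -> None:
        self.eye = Eye(self.eye)
        recs = {StageLabel(k): list(v) for k, v in self.recordings.items()}
        if StageLabel.BASELINE not in recs or not recs[StageLabel.BASELINE]:
            raise ValidationError(
                f"session {self.animal_id}/{self.eye.value} has no BASELINE "
                "recordings")
        for stage, stacks in recs.items():
            if not stacks:
                raise ValidationError(f"stage {stage.value} listed but empty")
        self.recordings = recs
        self.rois = list(self.rois)

    @property
    def key(self) -> str:
        return f"{self.animal_id}/{self.eye.value}"

    @property
    def stages(self) -> List[StageLabel]:
        return [s for s in PROTOCOL_ORDER if s in self.recordings]

    def rois_labelled(self, label: ROILabel) -> List[ROI]:
        return [r for r in self.rois if r.label is label]

    @property
    def entire_roi(self) -> ROI:
        whole = self.rois_labelled(ROILabel.ENTIRE_IMAGE)
        if whole:
            return whole[0]
        meta = self.recordings[StageLabel.BASELINE][0].metadata
        return full_image_roi(meta.height, meta.width)


@dataclass(frozen=True)
class AveragedRegionMetrics(RegionMetrics):
    """Field-wise mean of per-recording RegionMetrics.

    Fields UNDEFINED in some recordings are averaged over the recordings in
    which they are defined; ``n_defined`` records those counts.  The mixture
    identity of a single map need not hold for the averages.
    """

    n_recordings: int = 0
    n_defined: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupSummary:
    stage: StageLabel
    parameter: str
    mean: float
    sd: float
    sem: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def single_recording_metrics(stack: MBRFrameStack, roi: ROI,
                             threshold: float = DEFAULT_THRESHOLD
                             ) -> RegionMetrics:
    """temporal mean -> threshold segmentation -> region metrics."""
    mean_map = temporal_mean(stack)
    seg = segment_by_threshold(mean_map, roi, threshold)
    return compute_region_metrics(mean_map, seg)


def average_recordings(stacks: Sequence[MBRFrameStack], roi: ROI,
                       threshold: float = DEFAULT_THRESHOLD
                       ) -> AveragedRegionMetrics:
    """Mean region metrics over repeated recordings of the same eye/stage.

    Each recording is reduced via its temporal-mean map; every defined field
    is then averaged arithmetically across recordings.  A field UNDEFINED in
    every recording stays UNDEFINED.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValidationError("average_recordings needs at least one stack")
    shapes = {s.shape for s in stacks}
    if len(shapes) > 1:
        raise ValidationError(f"recordings disagree in geometry: {shapes}")
    per_rec = [single_recording_metrics(s, roi, threshold) for s in stacks]

    def _mean_defined(values):
        defined = [v for v in values if v is not None]
        return (float(np.mean(defined)) if defined else None), len(defined)

    mv, n_mv = _mean_defined([m.mv for m in per_rec])
    mt, n_mt = _mean_defined([m.mt for m in per_rec])
    mv_mt, n_d = _mean_defined([m.mv_mt for m in per_rec])
    return AveragedRegionMetrics(
        mv=mv, mt=mt,
        ma=float(np.mean([m.ma for m in per_rec])),
        mv_mt=mv_mt,
        arbs=float(np.mean([m.arbs for m in per_rec])),
        n_vascular=float(np.mean([m.n_vascular for m in per_rec])),
        n_tissue=float(np.mean([m.n_tissue for m in per_rec])),
        threshold=float(threshold),
        n_recordings=len(per_rec),
        n_defined={"MV": n_mv, "MT": n_mt, "MV_MT": n_d,
                   "MA": len(per_rec), "ARBS": len(per_rec)},
    )


def reperfusion_gate(baseline: RegionMetrics, current: RegionMetrics,
                     parameter: Parameter = Parameter.MA,
                     tolerance: float = 0.20) -> bool:
    """True iff the current value is within +/-tolerance of baseline
    (inclusive boundary)."""
    parameter = Parameter(parameter)
    base = baseline.value(parameter)
    cur = current.value(parameter)
    if base is None or cur is None:
        raise ValidationError("gate parameter is UNDEFINED")
    if base <= 0:
        raise ValidationError("gate baseline must be positive")
    return abs(cur - base) / base <= tolerance


def _summary(values: Sequence[float], stage: StageLabel,
             parameter: str) -> GroupSummary:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError(f"no values to summarise for {stage}/{parameter}")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(stage=stage, parameter=parameter,
                        mean=float(arr.mean()), sd=sd,
                        sem=sd / math.sqrt(arr.size), n=int(arr.size))


def summarize_stage(sessions: Sequence[ProtocolSession], stage: StageLabel,
                    parameter: Parameter = Parameter.MA,
                    roi_label: ROILabel = ROILabel.VESSEL,
                    threshold: float = DEFAULT_THRESHOLD,
                    pooling: str = "vessel") -> GroupSummary:
    """Cohort mean/sd/sem of one parameter at one stage.

    For vessel or tissue ROIs the natural parameter is MA (the plain ROI
    mean); for the entire image any of MV/MT/MA/MV_MT/ARBS.  With
    ``pooling="vessel"`` every matching ROI contributes one value; with
    ``"eye"`` each session contributes the mean over its matching ROIs.
    """
    stage = StageLabel(stage)
    parameter = Parameter(parameter)
    values: List[float] = []
    for session in sessions:
        if stage not in session.recordings:
            continue
        stacks = session.recordings[stage]
        if roi_label is ROILabel.ENTIRE_IMAGE:
            rois = [session.entire_roi]
        else:
            rois = session.rois_labelled(roi_label)
        per_roi = []
        for roi in rois:
            agg = average_recordings(stacks, roi, threshold)
            v = agg.value(parameter, reported=True)
            if v is not None:
                per_roi.append(v)
        if not per_roi:
            continue
        if pooling == "vessel":
            values.extend(per_roi)
        else:
            values.append(float(np.mean(per_roi)))
    if not values:
        raise ValidationError(
            f"stage {stage.value} absent (or no {roi_label.value} ROI) in "
            "every session")
    return _summary(values, stage, parameter.value)


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Student's paired t-test on differences x - y, two-sided.

    Zero-variance differences are degenerate: the t statistic is signalled
    as +/-infinity with p = 0 for a nonzero mean difference, and as 0 with
    p = 1 when x equals y everywhere.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    d = x - y
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, n - 1, 1.0, n)
        return PairedTestResult(math.copysign(math.inf, mean), n - 1, 0.0, n)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(_stats.t.sf(abs(t), n - 1))
    return PairedTestResult(t_statistic=t, degrees_of_freedom=n - 1,
                            p_value=p, n_pairs=n)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares y = a + b*x with the two-sided slope t-test."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("linear fit needs at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValidationError("x is constant; slope undefined")
    if np.ptp(y) == 0.0:
        # flat response: zero slope and, by convention, zero explained
        # variance (scipy's r is 0/0 here)
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, p_value=1.0, n=int(x.size))
    res = _stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2,
                            p_value=float(res.pvalue), n=int(x.size))


def significance_marker(p: float, alpha: float = 0.05,
                        strong_alpha: float = 0.001) -> str:
    """'**' below the strong level, '*' below alpha, '' otherwise."""
    if p < strong_alpha:
        return "**"
    if p < alpha:
        return "*"
    return ""


@dataclass
class ProtocolReport:
    """Tabular outputs of :func:`run_full_analysis` (pandas DataFrames)."""

    session_metrics: pd.DataFrame
    pulse: pd.DataFrame
    perfusion_indices: pd.DataFrame
    gates: pd.DataFrame
    stage_summaries: pd.DataFrame
    paired_tests: pd.DataFrame
    standard_ranges: pd.DataFrame
    occlusion_li: pd.DataFrame
    regressions: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("session_metrics", "pulse", "perfusion_indices", "gates",
                     "stage_summaries", "paired_tests", "standard_ranges",
                     "occlusion_li", "regressions"):
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            df.to_json(out / f"{name}.json", orient="records", indent=1)


def _session_aggregates(session: ProtocolSession, config: AnalysisConfig
                        ) -> Dict[StageLabel, Dict[str, AveragedRegionMetrics]]:
    """Per-stage, per-ROI averaged metrics for one session."""
    out: Dict[StageLabel, Dict[str, AveragedRegionMetrics]] = {}
    rois = list(session.rois)
    if not any(r.label is ROILabel.ENTIRE_IMAGE for r in rois):
        rois.append(session.entire_roi)
    for stage in session.stages:
        stacks = session.recordings[stage]
        out[stage] = {
            roi.name: average_recordings(stacks, roi,
                                         config.segmentation_threshold)
            for roi in rois
        }
    return out


def run_full_analysis(sessions: Sequence[ProtocolSession],
                      config: AnalysisConfig = AnalysisConfig()
                      ) -> ProtocolReport:
    """Run the whole protocol analysis over a cohort of sessions.

    Per session: per-stage/per-ROI region metrics with VPE and perfusion-
    stage classification, per-ROI pulse metrics, perfusion indices of the
    occlusion stages, and the reperfusion-gate outcome (sessions failing the
    gate have their ICAO and REPERFUSE2 stages flagged and excluded from the
    cohort statistics).  Per cohort: stage summaries, paired t-tests against
    baseline, normal-pair standard ranges and inter-eye regressions
    from animals contributing both eyes, and occlusion laterality indices.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValidationError("no sessions to analyse")

    thr = config.segmentation_threshold
    aggregates = {s.key: _session_aggregates(s, config) for s in sessions}
    gate_rows, excluded = [], {}
    for s in sessions:
        agg = aggregates[s.key]
        entire = s.entire_roi.name
        gate_ok: Optional[bool] = None
        deviation = math.nan
        if StageLabel.REPERFUSE1 in agg:
            base = agg[StageLabel.BASELINE][entire]
            cur = agg[StageLabel.REPERFUSE1][entire]
            gate_ok = reperfusion_gate(base, cur, config.gate_parameter,
                                       config.gate_tolerance)
            bval = base.value(config.gate_parameter)
            cval = cur.value(config.gate_parameter)
            deviation = abs(cval - bval) / bval
        s.reperfusion_ok = gate_ok
        excluded[s.key] = (set() if gate_ok in (None, True)
                           else {StageLabel.ICAO, StageLabel.REPERFUSE2})
        gate_rows.append({
            "animal_id": s.animal_id, "eye": s.eye.value,
            "gate_parameter": config.gate_parameter.value,
            "relative_deviation": deviation,
            "tolerance": config.gate_tolerance,
            "reperfusion_ok": gate_ok,
        })

    # ---- per-session tables -------------------------------------------
    metric_rows, pulse_rows, pi_rows = [], [], []
    for s in sessions:
        agg = aggregates[s.key]
        entire_name = s.entire_roi.name
        for stage in s.stages:
            is_excluded = stage in excluded[s.key]
            for roi_name, m in agg[stage].items():
                roi = next((r for r in s.rois if r.name == roi_name), None)
                label = roi.label.value if roi else ROILabel.ENTIRE_IMAGE.value
                whole = roi_name == entire_name or (
                    roi is not None and roi.label in (ROILabel.ENTIRE_IMAGE,
                                                      ROILabel.ONH))
                row = {
                    "animal_id": s.animal_id, "eye": s.eye.value,
                    "stage": stage.value, "roi": roi_name, "roi_label": label,
                    "MV": m.mv_reported, "MT": m.mt, "MA": m.ma,
                    "MV_MT": m.mv_mt, "ARBS": m.arbs,
                    "VPE": compute_vpe(m) if whole else math.nan,
                    "stage_class": (classify_perfusion_stage(
                        m, config.stage_boundaries).name if whole else ""),
                    "excluded_by_gate": is_excluded,
                }
                metric_rows.append(row)
            # pulse metrics: vessel ROIs and the entire image
            for roi in (s.rois_labelled(ROILabel.VESSEL) + [s.entire_roi]):
                pm = [pulse_metrics(roi_timeseries(st, roi))
                      for st in s.recordings[stage]]
                pulse_rows.append({
                    "animal_id": s.animal_id, "eye": s.eye.value,
                    "stage": stage.value, "roi": roi.name,
                    "max_mean": float(np.mean([p.max_mean for p in pm])),
                    "mean_min": float(np.mean([p.mean_min for p in pm])),
                    "max_min": float(np.mean([p.max_min for p in pm])),
                    "excluded_by_gate": is_excluded,
                })
            if stage in (StageLabel.ECAO, StageLabel.ICAO):
                base = agg[StageLabel.BASELINE][entire_name]
                cur = agg[stage][entire_name]
                for par in _REGRESSION_PARAMETERS:
                    if base.value(par) is None or cur.value(par) is None:
                        continue
                    try:
                        pi = perfusion_index(base, cur, par)
                        complete = False
                    except CompleteOcclusion:
                        pi, complete = math.nan, True
                    pi_rows.append({
                        "animal_id": s.animal_id, "eye": s.eye.value,
                        "stage": stage.value, "parameter": par.value,
                        "perfusion_index": pi,
                        "complete_occlusion": complete,
                        "excluded_by_gate": stage in excluded[s.key],
                    })

    # ---- cohort statistics --------------------------------------------
    def _stage_values(stage: StageLabel, roi_label: ROILabel,
                      parameter: Parameter) -> Dict[Tuple[str, str], float]:
        """(session, roi) -> value, honouring gate exclusions and pooling."""
        out: Dict[Tuple[str, str], float] = {}
        for s in sessions:
            if stage not in s.recordings or stage in excluded[s.key]:
                continue
            agg = aggregates[s.key]
            if roi_label is ROILabel.ENTIRE_IMAGE:
                rois = [s.entire_roi.name]
            else:
                rois = [r.name for r in s.rois_labelled(roi_label)]
            vals = {}
            for rn in rois:
                v = agg[stage][rn].value(parameter, reported=True)
                if v is not None:
                    vals[rn] = v
            if not vals:
                continue
            if config.pooling == "vessel" and roi_label in (
                    ROILabel.VESSEL, ROILabel.TISSUE):
                for rn, v in vals.items():
                    out[(s.key, rn)] = v
            else:
                out[(s.key, "")] = float(np.mean(list(vals.values())))
        return out

    summary_groups = ([(ROILabel.VESSEL, Parameter.MA),
                       (ROILabel.TISSUE, Parameter.MA)] +
                      [(ROILabel.ENTIRE_IMAGE, p) for p in _LI_PARAMETERS])
    summary_rows, test_rows = [], []
    for roi_label, par in summary_groups:
        base_vals = _stage_values(StageLabel.BASELINE, roi_label, par)
        for stage in PROTOCOL_ORDER:
            vals = _stage_values(stage, roi_label, par)
            if not vals:
                continue
            gs = _summary(list(vals.values()), stage, par.value)
            summary_rows.append({
                "stage": stage.value, "roi_label": roi_label.value,
                "parameter": par.value, "mean": gs.mean, "sd": gs.sd,
                "sem": gs.sem, "n": gs.n,
            })
            if stage is StageLabel.BASELINE:
                continue
            common = sorted(set(vals) & set(base_vals))
            if len(common) >= 2:
                res = paired_t_test([vals[k] for k in common],
                                    [base_vals[k] for k in common])
                p = res.p_value
                if config.bonferroni:
                    p = min(1.0, p * (len(PROTOCOL_ORDER) - 1))
                test_rows.append({
                    "stage": stage.value, "roi_label": roi_label.value,
                    "parameter": par.value, "t": res.t_statistic,
                    "df": res.degrees_of_freedom, "p": p,
                    "n_pairs": res.n_pairs,
                    "significant": p < config.alpha,
                    "marker": significance_marker(p, config.alpha,
                                                  config.strong_alpha),
                })

    # ---- fellow-eye analyses ------------------------------------------
    by_animal: Dict[str, List[ProtocolSession]] = {}
    for s in sessions:
        by_animal.setdefault(s.animal_id, []).append(s)
    pairs = [v for v in by_animal.values() if len(v) == 2]

    range_rows, li_rows, reg_rows = [], [], []
    ranges: Dict[Parameter, StandardRange] = {}
    if pairs:
        base_metrics = {
            s.key: aggregates[s.key][StageLabel.BASELINE][s.entire_roi.name]
            for v in pairs for s in v}
        for par in _LI_PARAMETERS:
            lis = []
            for a, b in pairs:
                ma, mb = base_metrics[a.key], base_metrics[b.key]
                if ma.value(par) is None or mb.value(par) is None:
                    continue
                lis.append(laterality_index_normal(ma, mb, par).li)
            if lis:
                rng = standard_range(lis)
                ranges[par] = rng
                range_rows.append({
                    "parameter": par.value, "mean": rng.mean, "sd": rng.sd,
                    "lower": rng.lower, "upper": rng.upper, "n": rng.n,
                })
        # occlusion LI: each occluded eye's ECAO vs fellow baseline
        for a, b in pairs:
            for occ, fellow in ((a, b), (b, a)):
                if StageLabel.ECAO not in occ.recordings:
                    continue
                occ_m = aggregates[occ.key][StageLabel.ECAO][
                    occ.entire_roi.name]
                for par in _LI_PARAMETERS:
                    if (occ_m.value(par, reported=True) is None
                            or (base_metrics[fellow.key].value(par) or 0) <= 0):
                        continue
                    occ_rep = replace(occ_m, mv=occ_m.mv_reported)
                    li = laterality_index_occlusion(
                        occ_rep, base_metrics[fellow.key], par)
                    if par in ranges:
                        li = flag_abnormal(li, ranges[par])
                    li_rows.append({
                        "animal_id": occ.animal_id,
                        "occluded_eye": occ.eye.value,
                        "parameter": par.value, "li": li.li,
                        "abnormal": li.abnormal,
                    })
        # inter-eye regression at baseline: lower eye against higher eye
        for par in _REGRESSION_PARAMETERS:
            xs, ys = [], []
            for a, b in pairs:
                va = base_metrics[a.key].value(par)
                vb = base_metrics[b.key].value(par)
                if va is None or vb is None:
                    continue
                xs.append(max(va, vb))
                ys.append(min(va, vb))
            if len(xs) >= 3 and np.ptp(xs) > 0:
                res = linear_fit(xs, ys)
                reg_rows.append({
                    "parameter": par.value, "slope": res.slope,
                    "intercept": res.intercept, "r_squared": res.r_squared,
                    "p": res.p_value, "n": res.n,
                })

    def _df(rows, columns):
        return pd.DataFrame(rows, columns=columns)

    return ProtocolReport(
        session_metrics=_df(metric_rows, [
            "animal_id", "eye", "stage", "roi", "roi_label", "MV", "MT",
            "MA", "MV_MT", "ARBS", "VPE", "stage_class", "excluded_by_gate"]),
        pulse=_df(pulse_rows, ["animal_id", "eye", "stage", "roi",
                               "max_mean", "mean_min", "max_min",
                               "excluded_by_gate"]),
        perfusion_indices=_df(pi_rows, [
            "animal_id", "eye", "stage", "parameter", "perfusion_index",
            "complete_occlusion", "excluded_by_gate"]),
        gates=_df(gate_rows, ["animal_id", "eye", "gate_parameter",
                              "relative_deviation", "tolerance",
                              "reperfusion_ok"]),
        stage_summaries=_df(summary_rows, ["stage", "roi_label", "parameter",
                                           "mean", "sd", "sem", "n"]),
        paired_tests=_df(test_rows, ["stage", "roi_label", "parameter", "t",
                                     "df", "p", "n_pairs", "significant",
                                     "marker"]),
        standard_ranges=_df(range_rows, ["parameter", "mean", "sd", "lower",
                                         "upper", "n"]),
        occlusion_li=_df(li_rows, ["animal_id", "occluded_eye", "parameter",
                                   "li", "abnormal"]),
        regressions=_df(reg_rows, ["parameter", "slope", "intercept",
                                   "r_squared", "p", "n"]),
    )
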