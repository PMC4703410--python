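"""Derived stiffness metrics and the end-to-end analysis pipeline.

Turns corrected sweep tables into the quantities a rheometry study reports:
segmental Young's moduli from the axial stress-strain curve, the
G'-vs-compression curve and stiffening ratio, strain-softening statistics,
the G'-vs-axial-stress line fit, reversibility (hysteresis) ratios, and
normalized stress-relaxation curve comparisons.  ``run_pipeline`` applies
all of it to a directory of traces and writes per-sample and per-condition
reports with provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import corrections, oscillation
from .exceptions import ValidationError
from .io import RheometerTrace, read_dataset

__all__ = [
    "LineFit",
    "StiffnessSummary",
    "records_to_frame",
    "youngs_modulus_segments",
    "compression_curve",
    "stiffening_ratio",
    "softening_stats",
    "fit_g_vs_stress",
    "hysteresis_metric",
    "compare_relaxation_curves",
    "analyze_sample",
    "run_pipeline",
]

#: Reference shear amplitude at which the compression curve is read, 2%.
GAMMA_REF = 0.02


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class StiffnessSummary:
    """Derived metrics for one sample."""

    condition: str = ""
    seed: int = 0
    E_segments: list = field(default_factory=list)   # [((lam_a, lam_b), E_pa)]
    Gp_vs_lambda: pd.DataFrame | None = None
    stiffening_ratio: float = float("nan")
    softening: pd.DataFrame | None = None
    line_fit: LineFit | None = None
    hysteresis: list = field(default_factory=list)   # cycle_k / cycle_1
    relaxation_compare: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten the scalar metrics into one report row."""
        row = {
            "condition": self.condition,
            "seed": self.seed,
            "stiffening_ratio": self.stiffening_ratio,
        }
        if self.Gp_vs_lambda is not None and len(self.Gp_vs_lambda):
            base = self.Gp_vs_lambda.loc[
                self.Gp_vs_lambda["lam"].abs().idxmin(), "Gp_act_pa"
            ]
            row["Gp0_pa"] = float(base)
        if self.line_fit is not None:
            row.update(
                slope=self.line_fit.slope,
                intercept_pa=self.line_fit.intercept,
                r2=self.line_fit.r2,
            )
        for (la, lb), e in self.E_segments:
            row[f"E_{abs(la)*100:.0f}_{abs(lb)*100:.0f}_pa"] = e
        if self.softening is not None:
            sub = self.softening[np.isclose(self.softening["lam"], 0.0)]
            if len(sub):
                row["gamma_half_lam0"] = float(sub["gamma_half"].iloc[0])
                row["softening_end_ratio_lam0"] = float(sub["end_ratio"].iloc[0])
        for k, r in enumerate(self.hysteresis, start=2):
            row[f"cycle{k}_over_cycle1"] = r
        return row


def records_to_frame(records) -> pd.DataFrame:
    """Corrected records -> tidy sweep table (both _meas and _act columns)."""
    return pd.DataFrame(
        {
            "gamma0": [r.gamma0 for r in records],
            "omega_rad_s": [r.omega for r in records],
            "lam": [r.lam for r in records],
            "Gp_meas_pa": [r.Gp_meas for r in records],
            "Gpp_meas_pa": [r.Gpp_meas for r in records],
            "normal_force_n": [r.normal_force for r in records],
            "sigma_meas_pa": [r.sigma_meas for r in records],
            "Gp_act_pa": [r.Gp_act for r in records],
            "Gpp_act_pa": [r.Gpp_act for r in records],
            "sigma_act_pa": [r.sigma_act for r in records],
            "sigma_mmhg": [r.sigma_mmhg for r in records],
            "t_elapsed_s": [r.t_elapsed for r in records],
        }
    )


def youngs_modulus_segments(stress_strain_table: pd.DataFrame,
                            convention: str = "auto") -> list:
    """Segmental Young's moduli: slope of corrected axial stress between
    neighbouring axial levels.

    ``stress_strain_table`` must have columns ``lam`` and ``sigma_pa`` (or
    ``sigma_act_pa``).  With the signed convention (compression negative,
    auto-detected from negative strains or stresses) E = -d sigma/d lam,
    which is positive in compression; with the magnitude convention the
    strains are compressive magnitudes and E = d sigma / d|lam|.

    Returns ``[((lam_a, lam_b), E), ...]`` sorted by |lam|; a constant axial
    offset in the stress (e.g. the preload) cancels exactly.
    """
    tab = stress_strain_table.copy()
    col = "sigma_pa" if "sigma_pa" in tab.columns else "sigma_act_pa"
    if col not in tab.columns:
        raise ValidationError("table needs a sigma_pa/sigma_act_pa column")
    if len(tab) < 2:
        raise ValidationError("need >= 2 axial levels for segmental E")
    lam = tab["lam"].to_numpy(dtype=float)
    sigma = tab[col].to_numpy(dtype=float)
    if np.unique(np.round(lam, 9)).size != lam.size:
        raise ValidationError("duplicate axial-strain levels")
    order = np.argsort(np.abs(lam))
    lam, sigma = lam[order], sigma[order]
    if convention == "auto":
        convention = "signed" if (np.any(lam < 0) or np.any(sigma < 0)) else "magnitude"
    segments = []
    for (la, sa), (lb, sb) in zip(zip(lam[:-1], sigma[:-1]), zip(lam[1:], sigma[1:])):
        if convention == "signed":
            e = -(sb - sa) / (lb - la)
        else:
            e = (sb - sa) / (abs(lb) - abs(la))
        segments.append(((float(la), float(lb)), float(e)))
    return segments


def compression_curve(corrected_records, gamma_ref: float = GAMMA_REF,
                      rtol: float = 0.25) -> pd.DataFrame:
    """G' (corrected) at the reference shear amplitude per axial level, from
    the last (most relaxed) time-sweep record at each level.

    Returns a table with columns ``lam, Gp_act_pa, Gpp_act_pa, sigma_act_pa,
    t_elapsed_s`` sorted by |lam|.
    """
    rows = [r for r in corrected_records
            if abs(r.gamma0 - gamma_ref) <= rtol * gamma_ref]
    if not rows:
        raise ValidationError(
            f"no records at reference shear amplitude {gamma_ref}"
        )
    df = records_to_frame(rows)
    df["_lam_key"] = df["lam"].round(9)
    df = (df.sort_values(["_lam_key", "t_elapsed_s"])
            .groupby("_lam_key", as_index=False).last())
    df = df.iloc[np.argsort(np.abs(df["lam"].to_numpy()))].reset_index(drop=True)
    return df[["lam", "Gp_act_pa", "Gpp_act_pa", "sigma_act_pa",
               "sigma_mmhg", "t_elapsed_s"]]


def stiffening_ratio(gp_vs_lambda: pd.DataFrame,
                     lam_ref: float = -0.25) -> float:
    """Compression-stiffening ratio G'(lam_ref) / G'(0)."""
    lam = gp_vs_lambda["lam"].to_numpy(dtype=float)
    sel0 = np.isclose(lam, 0.0, atol=1e-9)
    selc = np.isclose(lam, lam_ref, atol=1e-9)
    if not sel0.any() or not selc.any():
        raise ValidationError(
            f"compression curve must contain levels 0 and {lam_ref}"
        )
    g0 = float(gp_vs_lambda.loc[sel0, "Gp_act_pa"].iloc[0])
    gc = float(gp_vs_lambda.loc[selc, "Gp_act_pa"].iloc[0])
    return gc / g0


def softening_stats(strain_sweep_records) -> pd.DataFrame:
    """Per axial level: low-strain plateau G', the half-softening strain
    gamma_half (linear interpolation; NaN when G' never falls below half the
    plateau) and the end-to-start modulus ratio.

    gamma_half is the strain at which G' has fallen to half its low-strain
    plateau; a flat curve has no half-point and an end ratio of 1.
    """
    df = records_to_frame(strain_sweep_records) if not isinstance(
        strain_sweep_records, pd.DataFrame) else strain_sweep_records
    out = []
    for lam_key, sub in df.groupby(df["lam"].round(9)):
        sub = sub.sort_values("t_elapsed_s") if "t_elapsed_s" in sub else sub
        g = sub["gamma0"].to_numpy(dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValidationError(
                "strain-sweep grid must be strictly increasing within a level"
            )
        gp = sub["Gp_act_pa"].to_numpy(dtype=float)
        plateau = gp[0]
        half = plateau / 2.0
        gamma_half = float("nan")
        below = np.flatnonzero(gp < half)
        if below.size:
            j = below[0]
            if j == 0:
                gamma_half = g[0]
            else:
                frac = (gp[j - 1] - half) / (gp[j - 1] - gp[j])
                gamma_half = g[j - 1] + frac * (g[j] - g[j - 1])
        out.append({
            "lam": float(lam_key),
            "plateau_pa": float(plateau),
            "gamma_half": gamma_half,
            "end_ratio": float(gp[-1] / plateau) if plateau else float("nan"),
        })
    return pd.DataFrame(out).sort_values("lam", key=np.abs).reset_index(drop=True)


def fit_g_vs_stress(gp_vs_lambda: pd.DataFrame,
                    preload_pa: float = 0.0) -> LineFit:
    """Ordinary least squares of corrected G' on corrected axial stress
    across axial levels.

    ``preload_pa`` is subtracted from the stresses first, so the intercept
    estimates the modulus at zero deformation stress.
    """
    if len(gp_vs_lambda) < 3:
        raise ValidationError("need >= 3 axial levels for the G'-stress line")
    x = gp_vs_lambda["sigma_act_pa"].to_numpy(dtype=float) - preload_pa
    y = gp_vs_lambda["Gp_act_pa"].to_numpy(dtype=float)
    res = linregress(x, y)
    return LineFit(slope=float(res.slope), intercept=float(res.intercept),
                   r2=float(res.rvalue ** 2), n=len(x))


def hysteresis_metric(cycle_curves, damage_band=(0.8, 1.25)):
    """Per-cycle low-strain G' ratios relative to cycle 1.

    ``cycle_curves`` is a list of (cycle_index, low_strain_Gp) pairs or a
    DataFrame with columns ``cycle`` and ``Gp_act_pa`` (one up-sweep plateau
    value per cycle), in increasing cycle order.  Returns
    ``(ratios, damaged)`` where ratios[k] = cycle (k+2) / cycle 1 and
    ``damaged`` flags any ratio outside the configured band.
    """
    if isinstance(cycle_curves, pd.DataFrame):
        pairs = list(zip(cycle_curves["cycle"], cycle_curves["Gp_act_pa"]))
    else:
        pairs = list(cycle_curves)
    cycles = [int(c) for c, _ in pairs]
    if cycles != sorted(cycles) or len(set(cycles)) != len(cycles):
        raise ValidationError("cycles must be supplied in increasing order")
    if len(pairs) <= 1:
        return [], False
    base = float(pairs[0][1])
    ratios = [float(g) / base for _, g in pairs[1:]]
    damaged = any(not damage_band[0] <= r <= damage_band[1] for r in ratios)
    return ratios, damaged


def _relaxation_signal(trace: RheometerTrace):
    """Deformation-stress relaxation signal of a trace.

    For compression mode the normal force is converted to stress,
    geometrically corrected, and the preload offset is removed, leaving the
    relaxing deformation stress; for shear mode the shear-stress channel is
    used directly.
    """
    mode = trace.metadata.get("mode", "")
    if mode.startswith("compression"):
        d = trace.metadata.get("diameter_mm", oscillation.DEFAULT_DIAMETER_MM)
        lam = trace.metadata.get("lam", 0.0)
        sigma = corrections.correct_axial_stress(
            oscillation.normal_force_to_stress(trace.normal_force, d), lam
        )
        pre = corrections.preload_stress(trace.metadata.get("preload_g", 0.0), d)
        return trace.time, np.asarray(sigma) - pre
    return trace.time, trace.shear_stress


def compare_relaxation_curves(trace_a: RheometerTrace,
                              trace_b: RheometerTrace,
                              t_min: float = 5.0,
                              n_grid: int = 200) -> dict:
    """Compare two normalized stress-relaxation curves beyond ``t_min``.

    Both signals are resampled onto a common time grid restricted to
    ``t >= t_min``, normalized by their value at the first common grid point,
    and compared pointwise.  Early times are excluded because step-loading
    artifacts dominate there.  Returns max and mean absolute relative
    difference plus a paired summary (mean signed difference and its SD).
    """
    ta, ya = _relaxation_signal(trace_a)
    tb, yb = _relaxation_signal(trace_b)
    lo = max(ta.min(), tb.min(), t_min)
    hi = min(ta.max(), tb.max())
    if not hi > lo:
        raise ValidationError(
            "relaxation traces have no overlapping time range beyond t_min"
        )
    grid = np.linspace(lo, hi, n_grid)
    fa = np.interp(grid, ta, ya)
    fb = np.interp(grid, tb, yb)
    if fa[0] == 0 or fb[0] == 0:
        raise ValidationError("cannot normalize a zero-valued curve")
    na = fa / fa[0]
    nb = fb / fb[0]
    denom = np.maximum(np.abs(nb), 1e-12)
    rel = (na - nb) / denom
    return {
        "max_rel_diff": float(np.max(np.abs(rel))),
        "mean_rel_diff": float(np.mean(np.abs(rel))),
        "mean_signed_diff": float(np.mean(na - nb)),
        "sd_signed_diff": float(np.std(na - nb)),
        "t_min": float(lo),
        "n_grid": int(n_grid),
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _extract_corrected(traces, exponent: float = 2.0):
    recs = []
    for tr in traces:
        for r in oscillation.extract_sweep(tr):
            recs.append(corrections.correct_record(r, exponent))
    return recs


def analyze_sample(traces, preload_pa: float | None = None,
                   gamma_ref: float = GAMMA_REF,
                   correction_exponent: float = 2.0) -> StiffnessSummary:
    """Full per-sample analysis: extract, correct, and derive all metrics.

    ``traces`` is every trace recorded for one sample (time sweeps and
    amplitude sweeps across axial levels; optionally reversibility cycles
    and relaxation pairs).  ``preload_pa`` defaults to the preload stress
    implied by the trace metadata (mass and diameter).
    """
    traces = list(traces)
    if not traces:
        raise ValidationError("no traces supplied")
    meta0 = traces[0].metadata
    condition = meta0.get("phantom", {}).get("condition_label", "unknown")
    seed = meta0.get("phantom", {}).get("seed", 0)
    if preload_pa is None:
        mass = meta0.get("protocol", {}).get("preload_mass", 10.0)
        diam = meta0.get("phantom", {}).get("diameter", 20.0)
        preload_pa = corrections.preload_stress(mass, diam)

    time_traces = [t for t in traces if t.metadata.get("segment_kind") == "time_sweep"]
    sweep_traces = [t for t in traces if t.metadata.get("segment_kind") == "strain_sweep"]
    cyc_traces = [t for t in traces if t.metadata.get("segment_kind") == "reversibility"]
    rel_traces = [t for t in traces if t.metadata.get("segment_kind") == "relaxation"]

    summary = StiffnessSummary(condition=condition, seed=int(seed))

    if time_traces:
        recs = _extract_corrected(time_traces, correction_exponent)
        curve = compression_curve(recs, gamma_ref)
        summary.Gp_vs_lambda = curve
        if len(curve) >= 2:
            tab = curve.rename(columns={"sigma_act_pa": "sigma_pa"})
            summary.E_segments = youngs_modulus_segments(
                tab[["lam", "sigma_pa"]], convention="signed"
            )
        if len(curve) >= 3:
            summary.line_fit = fit_g_vs_stress(curve, preload_pa=preload_pa)
        try:
            summary.stiffening_ratio = stiffening_ratio(curve)
        except ValidationError:
            pass

    if sweep_traces:
        recs = _extract_corrected(sweep_traces, correction_exponent)
        summary.softening = softening_stats(recs)

    if cyc_traces:
        rows = []
        for tr in cyc_traces:
            if tr.metadata.get("direction") != "up":
                continue
            recs = _extract_corrected([tr], correction_exponent)
            low = min(recs, key=lambda r: r.gamma0)
            rows.append((int(tr.metadata["cycle"]), low.Gp_act))
        rows.sort(key=lambda p: p[0])
        ratios, damaged = hysteresis_metric(rows)
        summary.hysteresis = ratios
        summary.relaxation_compare.setdefault("damage_flag", damaged)

    if len(rel_traces) >= 2:
        by_mode: dict[str, list] = {}
        for tr in rel_traces:
            by_mode.setdefault(tr.metadata.get("mode", ""), []).append(tr)
        for mode, group in by_mode.items():
            if len(group) >= 2:
                group = sorted(group,
                               key=lambda t: t.metadata.get("diameter_mm", 0))
                summary.relaxation_compare[mode] = compare_relaxation_curves(
                    group[0], group[-1]
                )
    return summary


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(dataset, out_dir=None, config: dict | None = None) -> dict:
    """Analyze a dataset of traces grouped into samples.

    ``dataset`` is a directory of trace CSVs (with JSON sidecars) or a list
    of :class:`RheometerTrace`.  Traces are grouped into samples by
    (condition, phantom seed); each sample is analyzed with
    :func:`analyze_sample`; per-sample rows and per-condition aggregates
    (mean +/- SD across replicates) are returned and, when ``out_dir`` is
    given, written as ``samples.csv``, ``conditions.csv`` and
    ``provenance.json``.  Output is invariant to the input ordering.
    """
    config = dict(config or {})
    if isinstance(dataset, (str, Path)):
        traces = read_dataset(dataset)
    else:
        traces = list(dataset)
    groups: dict[tuple, list] = {}
    for tr in traces:
        ph = tr.metadata.get("phantom", {})
        key = (ph.get("condition_label", "unknown"), int(ph.get("seed", 0)))
        groups.setdefault(key, []).append(tr)

    summaries = {}
    rows = []
    for key in sorted(groups):
        summ = analyze_sample(
            groups[key],
            preload_pa=config.get("preload_pa"),
            gamma_ref=config.get("gamma_ref", GAMMA_REF),
            correction_exponent=config.get("correction_exponent", 2.0),
        )
        summaries[key] = summ
        rows.append(summ.to_row())
    samples = pd.DataFrame(rows)
    numeric = samples.select_dtypes("number").columns.difference(["seed"])
    conditions = samples.groupby("condition")[list(numeric)].agg(["mean", "std", "count"])

    result = {"samples": samples, "conditions": conditions,
              "summaries": summaries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        samples.to_csv(out_dir / "samples.csv", index=False)
        conditions.to_csv(out_dir / "conditions.csv")
        prov = {
            "config": config,
            "config_hash": _config_hash(config),
            "n_traces": len(traces),
            "samples": [
                {"condition": c, "seed": s} for c, s in sorted(groups)
            ],
        }
        with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(prov, fh, indent=1, sort_keys=True)
        with open(out_dir / "pipeline.log", "w", encoding="utf-8") as fh:
            fh.write(
                f"analyzed {len(traces)} traces in {len(groups)} samples\n"
            )
    return result
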