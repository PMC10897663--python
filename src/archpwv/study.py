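"""End-to-end in-silico study orchestration.

Simulates a cohort of specimens in the Type I and Type III arch
configurations, filters the stent-eligible subgroup and repeats both
configurations after stent-graft deployment, runs every acquisition through
the measurement pipeline (cross-correlation transit time, calibrated
centerline length at MAP, PWV), and applies the paired statistical layer.
Pairing is within-specimen: the same sample parameters are reused across
configurations with only configuration deltas, mirroring the bench protocol
of re-mounting the same aorta.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .biostats import PairedComparison, paired_compare
from .centerline import length_from_point_sets
from .errors import ArchPWVError
from .hemodynamics import compute_pwv, eligibility_bounds, percent_change
from .mockloop import (AortaSample, CohortPopulation, MockLoopConfig,
                       draw_cardiac_output, generate_cohort,
                       generate_point_set, simulate_sample)
from .waveform import estimate_transit_time, pressure_summary

__all__ = [
    "CohortSummary",
    "filter_eligible",
    "run_study",
    "report",
    "CONFIG_LABELS",
]

CONFIG_LABELS = ("typeI_native", "typeIII_native",
                 "typeI_stented", "typeIII_stented")
VARIABLES = ("flow_lpm", "dbp_mmhg", "sbp_mmhg", "pp_mmhg", "map_mmhg",
             "pwv_m_s")
CALIBRATION_PRESSURES_MMHG = (80.0, 100.0, 120.0)


@dataclass(frozen=True)
class CohortSummary:
    """Aggregated outputs of one simulated study."""

    n_total: int
    n_eligible: int
    seed: int
    samples: pd.DataFrame          # per-specimen baseline characteristics
    per_sample: pd.DataFrame       # one row per specimen x configuration
    aggregates: pd.DataFrame       # mean/SD per configuration and variable
    comparisons: pd.DataFrame      # paired contrasts (Table-2-like)
    percent_changes: pd.DataFrame  # both percent-change estimands
    failures: tuple = ()

    def __post_init__(self) -> None:
        if self.n_eligible > self.n_total:
            raise ValueError("n_eligible cannot exceed n_total")


def filter_eligible(cohort, d_graft_mm: float = 26.0,
                    lo: float = 0.10, hi: float = 0.20) -> list:
    """Specimens whose landing-zone (point 2) diameter permits lo-hi oversizing."""
    d_min, d_max = eligibility_bounds(d_graft_mm, lo, hi)
    return [s for s in cohort if d_min <= s.d2_mm <= d_max]


def _sub_seed(seed: int, *ids: int) -> int:
    ss = np.random.SeedSequence((int(seed),) + tuple(int(i) for i in ids))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def acquire(sample: AortaSample, config: MockLoopConfig, *,
            jitter_px: float = 1.0, px_per_cm: float = 40.0,
            n_points: int = 20) -> dict:
    """One full acquisition: simulate, then measure through the pipeline."""
    sim = simulate_sample(sample, config)
    tt = estimate_transit_time(sim.proximal_flow, sim.distal_flow,
                               min_cycles=min(25, config.n_cycles))
    press = pressure_summary(sim.zone3_pressure)
    delta = config.arch_length_delta_cm if config.arch_type == "III" else 0.0
    point_sets = [
        generate_point_set(sample, p, px_per_cm=px_per_cm,
                           jitter_px=jitter_px, n_points=n_points,
                           seed=_sub_seed(config.seed, 100 + i),
                           length_delta_cm=delta)
        for i, p in enumerate(CALIBRATION_PRESSURES_MMHG)
    ]
    fit = length_from_point_sets(point_sets)
    length_cm = fit.length_at(press.map_mmhg)
    pwv = compute_pwv(length_cm / 100.0, tt.transit_time_s)
    return {
        "flow_lpm": float(np.mean(sim.proximal_flow.values)),
        "dbp_mmhg": press.dbp_mmhg,
        "sbp_mmhg": press.sbp_mmhg,
        "pp_mmhg": press.pp_mmhg,
        "map_mmhg": press.map_mmhg,
        "transit_time_s": tt.transit_time_s,
        "peak_correlation": tt.peak_correlation,
        "length_cm": length_cm,
        "length_at_100_cm": fit.length_at(100.0),
        "pwv_m_s": pwv.pwv_m_s,
        # effective PWV truth: with a stent the whole-aorta PWV exceeds the
        # native wall wave speed because the covered segment is faster
        "true_pwv_m_s": (sim.truth.length_at_map_cm / 100.0
                         / sim.truth.transit_time_s),
        "true_wave_speed_m_s": sim.truth.wave_speed_m_s,
        "true_transit_time_s": sim.truth.transit_time_s,
    }


def run_study(n: int = 24, base_config: MockLoopConfig | None = None,
              population: CohortPopulation | None = None, seed: int = 0, *,
              d_graft_mm: float = 26.0, oversizing=(0.10, 0.20),
              jitter_px: float = 1.0, px_per_cm: float = 40.0) -> CohortSummary:
    """Simulate and analyze a full paired cohort study.

    Every specimen is acquired natively in both arch configurations; the
    stent-eligible subgroup is re-acquired in both configurations with the
    stent deployed.  Acquisition seeds are deterministic substreams of
    ``seed``.  Specimens whose simulation or pipeline fails are excluded
    listwise with a recorded reason.
    """
    base = base_config or MockLoopConfig()
    pop = population or CohortPopulation()
    cohort = generate_cohort(n, pop, seed=_sub_seed(seed, 0))
    eligible_ids = {s.sample_id for s in
                    filter_eligible(cohort, d_graft_mm, *oversizing)}
    co_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 23)))

    rows, failures = [], []
    for i, sample in enumerate(cohort):
        co = draw_cardiac_output(pop, co_rng)
        configs = [("typeI_native", dict(arch_type="I", stent=False)),
                   ("typeIII_native", dict(arch_type="III", stent=False))]
        if sample.sample_id in eligible_ids:
            configs += [("typeI_stented", dict(arch_type="I", stent=True)),
                        ("typeIII_stented", dict(arch_type="III", stent=True))]
        try:
            for j, (label, delta) in enumerate(configs):
                cfg = replace(base, cardiac_output_lpm=co,
                              seed=_sub_seed(seed, i + 1, j), **delta)
                row = acquire(sample, cfg, jitter_px=jitter_px,
                              px_per_cm=px_per_cm)
                row.update(sample_id=sample.sample_id, configuration=label,
                           eligible=sample.sample_id in eligible_ids)
                rows.append(row)
        except ArchPWVError as exc:
            failures.append((sample.sample_id, str(exc)))
            rows = [r for r in rows if r["sample_id"] != sample.sample_id]

    per_sample = pd.DataFrame(rows)
    samples_df = pd.DataFrame([{
        "sample_id": s.sample_id, "d1_mm": s.d1_mm, "d2_mm": s.d2_mm,
        "d3_mm": s.d3_mm, "d4_mm": s.d4_mm,
        "length_ref_cm": s.length_ref_cm,
        "oversizing_pct": 100.0 * (d_graft_mm / s.d2_mm - 1.0),
        "eligible": s.sample_id in eligible_ids,
    } for s in cohort])

    ok_ids = set(per_sample["sample_id"]) if len(per_sample) else set()
    summary = CohortSummary(
        n_total=n,
        n_eligible=len(eligible_ids & ok_ids),
        seed=int(seed),
        samples=samples_df,
        per_sample=per_sample,
        aggregates=_aggregate(per_sample),
        comparisons=_comparisons(per_sample),
        percent_changes=_percent_changes(per_sample),
        failures=tuple(failures),
    )
    return summary


def _aggregate(per_sample: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for label in CONFIG_LABELS:
        sub = per_sample[per_sample["configuration"] == label] \
            if len(per_sample) else per_sample
        for var in VARIABLES:
            if len(sub) == 0:
                rows.append({"configuration": label, "variable": var,
                             "n": 0, "mean": np.nan, "sd": np.nan})
            else:
                rows.append({"configuration": label, "variable": var,
                             "n": len(sub), "mean": float(sub[var].mean()),
                             "sd": float(sub[var].std(ddof=1))})
    return pd.DataFrame(rows)


def _paired_frames(per_sample: pd.DataFrame, label_a: str, label_b: str):
    a = per_sample[per_sample["configuration"] == label_a].set_index("sample_id")
    b = per_sample[per_sample["configuration"] == label_b].set_index("sample_id")
    common = a.index.intersection(b.index)
    return a.loc[common], b.loc[common]


def _compare_rows(per_sample, block, label_a, label_b, variables):
    rows = []
    a, b = _paired_frames(per_sample, label_a, label_b)
    for var in variables:
        row = {"block": block, "variable": var,
               "config_a": label_a, "config_b": label_b, "n": len(a)}
        if len(a) >= 3:
            cmp: PairedComparison = paired_compare(a[var].to_numpy(),
                                                   b[var].to_numpy())
            row.update(mean_a=cmp.mean_sd_a[0], sd_a=cmp.mean_sd_a[1],
                       mean_b=cmp.mean_sd_b[0], sd_b=cmp.mean_sd_b[1],
                       p_value=cmp.p_value, test=cmp.test_used)
        else:
            row.update(mean_a=np.nan, sd_a=np.nan, mean_b=np.nan,
                       sd_b=np.nan, p_value=np.nan, test="NA")
        rows.append(row)
    return rows


def _comparisons(per_sample: pd.DataFrame) -> pd.DataFrame:
    if len(per_sample) == 0:
        return pd.DataFrame(columns=["block", "variable", "config_a",
                                     "config_b", "n", "mean_a", "sd_a",
                                     "mean_b", "sd_b", "p_value", "test"])
    rows = _compare_rows(per_sample, "primary",
                         "typeI_native", "typeIII_native", VARIABLES)
    rows += _compare_rows(per_sample, "subgroup_stented",
                          "typeI_stented", "typeIII_stented", VARIABLES)
    rows += _compare_rows(per_sample, "secondary_typeI",
                          "typeI_native", "typeI_stented", ("pwv_m_s",))
    rows += _compare_rows(per_sample, "secondary_typeIII",
                          "typeIII_native", "typeIII_stented", ("pwv_m_s",))
    return pd.DataFrame(rows)


PERCENT_CONTRASTS = (
    ("arch_native", "typeI_native", "typeIII_native"),
    ("tevar_typeI", "typeI_native", "typeI_stented"),
    ("tevar_typeIII", "typeIII_native", "typeIII_stented"),
    ("arch_stented", "typeI_stented", "typeIII_stented"),
)


def _percent_changes(per_sample: pd.DataFrame) -> pd.DataFrame:
    """PWV percent change, reported under both estimands.

    ``mean_of_ratios``: mean over specimens of per-specimen percent change
    (the estimand behind within-pair summaries); ``ratio_of_means``: percent
    change of the configuration means (what a reader recomputes from a
    summary table).  The two differ in general.
    """
    rows = []
    for name, label_a, label_b in PERCENT_CONTRASTS:
        a, b = (_paired_frames(per_sample, label_a, label_b)
                if len(per_sample) else (per_sample, per_sample))
        row = {"contrast": name, "config_a": label_a, "config_b": label_b,
               "n": len(a)}
        if len(a) >= 2:
            pct = np.array([percent_change(x, y) for x, y in
                            zip(a["pwv_m_s"], b["pwv_m_s"])])
            row.update(
                mean_of_ratios_pct=float(pct.mean()),
                sd_of_ratios_pct=float(pct.std(ddof=1)),
                ratio_of_means_pct=percent_change(
                    float(a["pwv_m_s"].mean()), float(b["pwv_m_s"].mean())))
        else:
            row.update(mean_of_ratios_pct=np.nan, sd_of_ratios_pct=np.nan,
                       ratio_of_means_pct=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

TABLE1_ROWS = (
    ("Diameter point 1 (mm)", "d1_mm"),
    ("Diameter point 2 (mm)", "d2_mm"),
    ("Diameter point 3 (mm)", "d3_mm"),
    ("Diameter point 4 (mm)", "d4_mm"),
    ("Centreline length, Type I arch (cm)", "length_ref_cm"),
)
TABLE2_COLUMNS = ("block", "variable", "config_a", "config_b", "n",
                  "mean_a", "sd_a", "mean_b", "sd_b", "p_value", "test")


def report(summary: CohortSummary, out_dir) -> dict:
    """Write Table-1/Table-2-style CSVs, boxplots, and a full-precision JSON.

    Returns a dict mapping artifact names to written paths.  With an empty
    eligible subgroup the subgroup columns are emitted as NA with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    if summary.n_eligible == 0:
        warnings.warn("eligible subgroup is empty: subgroup columns are NA",
                      stacklevel=2)

    t1_rows = []
    s = summary.samples
    sub = s[s["eligible"]] if len(s) else s
    for label, col in TABLE1_ROWS:
        t1_rows.append({
            "variable": label,
            "primary_mean": float(s[col].mean()) if len(s) else np.nan,
            "primary_sd": float(s[col].std(ddof=1)) if len(s) > 1 else np.nan,
            "subgroup_mean": float(sub[col].mean()) if len(sub) else np.nan,
            "subgroup_sd": float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan,
        })
    paths["table1"] = out / "table1.csv"
    pd.DataFrame(t1_rows).to_csv(paths["table1"], index=False)

    t2 = summary.comparisons.reindex(columns=TABLE2_COLUMNS)
    paths["table2"] = out / "table2.csv"
    t2.to_csv(paths["table2"], index=False)

    paths["percent_changes"] = out / "percent_changes.csv"
    summary.percent_changes.to_csv(paths["percent_changes"], index=False)

    payload = {
        "n_total": summary.n_total,
        "n_eligible": summary.n_eligible,
        "seed": summary.seed,
        "failures": list(summary.failures),
        "samples": summary.samples.to_dict(orient="records"),
        "per_sample": summary.per_sample.to_dict(orient="records"),
        "aggregates": summary.aggregates.to_dict(orient="records"),
        "comparisons": summary.comparisons.to_dict(orient="records"),
        "percent_changes": summary.percent_changes.to_dict(orient="records"),
    }
    paths["json"] = out / "summary.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True)

    if len(summary.per_sample):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        ps = summary.per_sample
        for ax, var, title in zip(axes, ("pwv_m_s", "map_mmhg"),
                                  ("PWV (m/s)", "MAP (mmHg)")):
            data, labels = [], []
            for label in CONFIG_LABELS:
                vals = ps.loc[ps["configuration"] == label, var]
                if len(vals):
                    data.append(vals.to_numpy())
                    labels.append(label.replace("type", ""))
            ax.boxplot(data, tick_labels=labels)
            ax.set_title(title)
            ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        paths["boxplots"] = out / "boxplots.png"
        fig.savefig(paths["boxplots"], dpi=100)
        plt.close(fig)

    return paths
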