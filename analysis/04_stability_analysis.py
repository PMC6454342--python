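#!/usr/bin/env python
"""Temporal-stability and addiction-correlation analyses.

Reads ``daily_params.csv`` and ``spai5.csv`` and writes, per parameter:

* ``unit_stability.csv``  — each 1/2/4-week block's across-user correlation
  with the 2-month mean (the fundamental-time-unit analysis),
* ``cycle_stability.csv`` — mean across-user correlation of two independent
  blocks at each time interval TI (the independent-cycle analysis),
* ``addiction_corr.csv``  — 2-month parameter means vs the SPAI-5 total,
* ``intercorrelation.csv`` — the 7x7 parameter correlation matrix,
* ``stability_summary.json`` — threshold flags and headline numbers,

plus (if matplotlib is importable) ``fig_unit_stability.png`` and
``fig_cycle_stability.png``.
"""

import argparse
import json
from pathlib import Path

from screenuse import (
    StudyConfig,
    read_daily_parameters,
    read_spai5,
    run_stability_suite,
)


def _plots(results, out_dir: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib not available; skipping figures")
        return
    unit = results["unit_stability"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    for ax, u in zip(axes, (1, 2, 4)):
        sub = unit[unit["unit_weeks"] == u]
        for param, grp in sub.groupby("parameter"):
            ax.plot(grp["first_week"], grp["r"], marker="o", label=param)
        ax.axhline(0.75, color="grey", ls="--", lw=0.8)
        ax.set_title(f"{u}-week units vs 2 months")
        ax.set_xlabel("first week of unit")
    axes[0].set_ylabel("Pearson r across users")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "fig_unit_stability.png", dpi=150)

    cycle = results["cycle_stability"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, u in zip(axes, (1, 2)):
        sub = cycle[cycle["unit_weeks"] == u]
        for param, grp in sub.groupby("parameter"):
            ax.plot(grp["TI"], grp["mean_r"], marker="o", label=param)
        ax.axhline(0.75, color="grey", ls="--", lw=0.8)
        ax.set_title(f"{u}-week periods")
        ax.set_xlabel("time interval TI (weeks)")
    axes[0].set_ylabel("mean r across users")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "fig_cycle_stability.png", dpi=150)
    print(f"wrote figures to {out_dir}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--daily", type=Path, default=Path("results/daily_params.csv"))
    parser.add_argument("--spai5", type=Path, default=Path("results/spai5.csv"))
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    config = StudyConfig.from_toml(args.config) if args.config else StudyConfig()
    daily = read_daily_parameters(args.daily)
    spai, rejected = read_spai5(args.spai5) if args.spai5.exists() else (None, None)
    results = run_stability_suite(daily, spai, config)

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    results["unit_stability"].to_csv(out / "unit_stability.csv", index=False)
    results["cycle_stability"].to_csv(out / "cycle_stability.csv", index=False)
    results["intercorrelation"].to_csv(out / "intercorrelation.csv")
    if spai is not None:
        results["addiction_correlations"].to_csv(out / "addiction_corr.csv", index=False)

    unit = results["unit_stability"]
    summary = {
        "high_corr_threshold": config.high_corr_threshold,
        "n_users": int(daily["user_id"].nunique()),
        "n_user_days": int(len(daily)),
        "unit_high_fraction": {
            str(u): float(unit[unit["unit_weeks"] == u]["high"].mean())
            for u in (1, 2, 4)
        },
        "unit_mean_r": {
            str(u): float(unit[unit["unit_weeks"] == u]["r"].mean()) for u in (1, 2, 4)
        },
    }
    cycle = results["cycle_stability"]
    one_wk = cycle[cycle["unit_weeks"] == 1]
    summary["cycle_mean_r_by_ti_1wk"] = {
        str(ti): float(grp["mean_r"].mean()) for ti, grp in one_wk.groupby("TI")
    }
    if spai is not None:
        ac = results["addiction_correlations"].set_index("parameter")
        summary["r_pd_spai5"] = float(ac.loc["PD", "r"])
        summary["p_pd_spai5"] = float(ac.loc["PD", "p_value"])
    (out / "stability_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    for u in (1, 2, 4):
        sub = unit[unit["unit_weeks"] == u]
        print(
            f"{u}-week units: mean r {sub['r'].mean():.3f}; "
            f"{100 * sub['high'].mean():.0f}% of cells at r>={config.high_corr_threshold}"
        )
    tis = summary["cycle_mean_r_by_ti_1wk"]
    print("1-week independent cycles, mean r by TI: "
          + ", ".join(f"TI{ti}={v:.3f}" for ti, v in tis.items()))
    if spai is not None:
        print(f"r(PD, SPAI-5) = {summary['r_pd_spai5']:.3f} (p = {summary['p_pd_spai5']:.3f})")
    print(f"wrote tables and stability_summary.json to {out}")
    _plots(results, out)


if __name__ == "__main__":
    main()
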