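#!/usr/bin/env python
"""Run the behavioral pipeline on the simulated trials: filter, code
accuracy, compute deviation scores, summarize the 17 collapsed conditions,
and run the strength-difference and fast/slow median-split analyses.

Reads results/trials.csv (from 02_simulate_experiment.py); writes
results/summary.csv, results/removals.json, results/strength_difference.csv,
results/median_split.csv and results/fig_summary.png.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from mcia import analysis as ba

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    trials = ba.read_trials(RESULTS / "trials.csv")
    coded = ba.code_accuracy(trials)
    kept, report = ba.filter_trials(coded)
    print(
        f"filtered {report['n_removed']}/{report['n_input']} trials "
        f"({100 * report['fraction_removed']:.1f}%): {report['by_reason']}"
    )

    devs = ba.deviation_scores(kept)
    summary = ba.summarize_conditions(kept, devs)
    summary.to_csv(RESULTS / "summary.csv")
    (RESULTS / "removals.json").write_text(json.dumps(report, indent=2))

    t = summary.table
    tog = t[t["format"] == "together"]
    spl = t[t["format"] == "split"]
    print(f"mean accuracy   together {tog['acc_mean'].mean():.3f} "
          f"vs split {spl['acc_mean'].mean():.3f}")
    print(f"mean deviation  together {tog['dev_mean'].mean():+.3f} "
          f"vs split {spl['dev_mean'].mean():+.3f} "
          "(negative = dilution)")

    sd = ba.strength_difference_table(devs)
    sd.to_csv(RESULTS / "strength_difference.csv", index=False)
    trend = sd.groupby("strength_diff")["deviation"].mean()
    print("deviation by strength difference (equal -> two-step):")
    for code in (-1, 0, 1):
        print(f"  {code:+d}: {trend.get(code, float('nan')):+.3f}")

    ms = ba.median_split(devs)
    ms.to_csv(RESULTS / "median_split.csv", index=False)
    overall = ms[ms["format"] == "all"].pivot_table(
        index="participant", columns="speed", values="deviation"
    )
    print(f"median split: fast {overall['fast'].mean():+.3f} "
          f"vs slow {overall['slow'].mean():+.3f}")

    _plot(summary)
    print(f"wrote summary + figure under {RESULTS}/")


def _plot(summary):
    t = summary.table
    conds = ["ww", "wm", "ws", "mm", "ms", "ss", "wom"]
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    for ax, (col, sem_col, label) in zip(
        axes,
        [("acc_mean", "acc_sem", "accuracy"),
         ("rt_mean", "rt_sem", "mean RT (ms)"),
         ("dev_mean", "dev_sem", "deviation score")],
    ):
        for fmt, marker in (("together", "o"), ("split", "s")):
            sub = t[t["format"] == fmt].set_index("condition").loc[conds]
            ax.errorbar(
                range(len(conds)), sub[col], yerr=sub[sem_col],
                marker=marker, capsize=3, label=fmt,
            )
        if col != "dev_mean":
            half = t[t["format"] == "half"].set_index("condition").loc[["w", "m", "s"]]
            ax.errorbar(
                [len(conds) + 0.5 + i * 0.3 for i in range(3)],
                half[col], yerr=half[sem_col],
                marker="^", linestyle="none", capsize=3, label="half",
            )
        else:
            ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
    axes[-1].set_xticks(range(len(conds)))
    axes[-1].set_xticklabels(conds)
    fig.tight_layout()
    fig.savefig(RESULTS / "fig_summary.png", dpi=120)


if __name__ == "__main__":
    main()
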