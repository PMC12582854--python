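"""Recovery benchmark of the LD estimator under decline and equilibrium.

Simulates the full design grid (bottleneck-decline and equilibrium
demographies x mutation rates 0.4e-8 and 1.1e-8, true rate 0.85 cM/Mb,
five diploids, ten replicates) on a 200 kb region and reports per-
combination mean/median estimates, bias, and ratio to truth before any
rescaling. Whether the estimator under-estimates under decline is
reported, not asserted.
"""

from _common import RESULTS, SEED
from ratemaps import io
from ratemaps.ldrec import BenchmarkConfig, benchmark_estimator


def main() -> None:
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)
    config = BenchmarkConfig(region_length=200_000, table_reps=4000)
    bench = benchmark_estimator(config, seed=SEED)
    io.write_map_table(out / "benchmark.tsv", bench)
    summary = (
        bench.groupby(["demography", "mu"])
        .first()[["mean", "median", "bias", "ratio_to_truth"]]
        .reset_index()
    )
    print(f"design: {len(config.demographies)} demographies x "
          f"{len(config.mutation_rates)} mutation rates x {config.replicates} replicates, "
          f"{config.region_length/1e3:.0f} kb region, truth {config.true_rate_cm_mb} cM/Mb")
    print(summary.to_string(index=False))
    eq = summary[summary["demography"] == "equilibrium"]["ratio_to_truth"]
    de = summary[summary["demography"] == "bottleneck_decline"]["ratio_to_truth"]
    print(f"median/truth — equilibrium: {', '.join(f'{r:.2f}' for r in eq)}; "
          f"decline: {', '.join(f'{r:.2f}' for r in de)}")


if __name__ == "__main__":
    main()
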