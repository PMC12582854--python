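"""Multi-scale (Haar) wavelet correlations of rates with genomic features.

Bins diversity, divergence, recombination, GC content and exon content at
1 kb, decomposes the scaffold halves with the orthonormal Haar pyramid,
and writes per-scale Kendall correlations and through-origin linear-model
reports.
"""

from _common import MU_CONVERSION, RESULTS, SCAFFOLD_LENGTH, SEED, simulated_inputs
from ratemaps import io
from ratemaps.divmut import build_accessibility_mask, windowed_divergence, windowed_diversity
from ratemaps.intervals import AccessibilityMask
from ratemaps.ldrec import estimate_map
from ratemaps.twolocus import build_two_locus_table
from ratemaps.wavescale import (
    bin_feature_tracks,
    kendall_detail_correlations,
    log_transform_rates,
    scale_linear_models,
    split_halves,
)

import pandas as pd


def main() -> None:
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)
    spec, model, mu_track, rec_track, subs, panel, annots, motifs = simulated_inputs()
    scaf = spec.names[0]

    callable_mask = AccessibilityMask.full({scaf: SCAFFOLD_LENGTH})
    mask = build_accessibility_mask(annots, callable_mask, flank=10_000,
                                    scaffold_lengths={scaf: SCAFFOLD_LENGTH})
    pi = windowed_diversity(panel, mask, 1000)
    div = windowed_divergence(subs, {scaf: panel.positions}, mask, 1000,
                              scaffold_lengths={scaf: SCAFFOLD_LENGTH})
    table = build_two_locus_table(panel.n_hap, model, reps=3000, seed=SEED + 20)
    rec = estimate_map(panel, table, MU_CONVERSION, window=100_000)

    tracks = bin_feature_tracks(
        scaf, SCAFFOLD_LENGTH,
        sequence=spec.sequence(scaf, seed=SEED + 5),
        exons=annots.get(scaf),
        pi=pi, divergence=div.table, recombination=rec.table,
        mask=mask,
    )
    halves = {name: split_halves(tr) for name, tr in tracks.items()}
    reports = []
    for side, idx in (("left", 0), ("right", 1)):
        dec = {name: h[idx] for name, h in halves.items()}
        rep = kendall_detail_correlations(dec, alpha=0.01)
        rep.insert(0, "half", side)
        reports.append(rep)
    kendall = pd.concat(reports, ignore_index=True)
    io.write_map_table(out / "wavelet_kendall.tsv", kendall)

    # linear models on log-transformed rate tracks (GC/exon untransformed)
    lm_tracks = dict(tracks)
    for name in ("recombination", "diversity", "divergence"):
        lm_tracks[name] = log_transform_rates(tracks[name])
    lm_halves = {name: split_halves(tr)[0] for name, tr in lm_tracks.items()}
    lm_halves = {n.replace("_log", ""): d for n, d in lm_halves.items()}
    for d in lm_halves.values():
        d.name = d.name.replace("_log", "")
    lm = scale_linear_models(lm_halves)
    io.write_map_table(out / "wavelet_linear_models.tsv", lm)

    n_levels = halves["gc"][0].levels
    sig = kendall[kendall["significant"]]
    print(f"tracks: {', '.join(tracks)}; half length {2**n_levels} bins, "
          f"scales 2-{2**n_levels} kb")
    print(f"significant Kendall correlations at the 1% level: {len(sig)}/{len(kendall)}")
    if len(sig):
        top = sig.reindex(sig.tau.abs().sort_values(ascending=False).index).head(5)
        print(top[["half", "scale_kb", "a", "b", "tau", "p"]].to_string(index=False))
    print("linear models (through the origin), adjusted R^2 by scale:")
    print(lm.groupby("scale_kb")["adj_r2"].first().to_string())


if __name__ == "__main__":
    main()
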