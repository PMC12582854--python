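"""Simulate every synthetic input the downstream analyses consume.

Writes substitutions (BED), the SNP panel (VCF), exon annotations (GFF3),
hotspot-motif placements (BED) and the ground-truth rate tracks (bedGraph)
under results/synthetic/.
"""

import pandas as pd

from _common import RESULTS, simulated_inputs
from ratemaps import io
from ratemaps.variants import PolymorphismSet


def main() -> None:
    out = RESULTS / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    spec, model, mu_track, rec_track, subs, panel, annots, motifs = simulated_inputs()
    scaf = spec.names[0]

    io.write_substitutions_bed(out / "substitutions.bed", subs)
    io.write_vcf(out / "panel.vcf", PolymorphismSet.from_panel(panel))
    io.write_gff3(out / "annotations.gff3", annots)
    io.write_motifs_bed(out / "motifs.bed", motifs)
    for name, track in (("mu", mu_track), ("rec", rec_track)):
        df = pd.DataFrame(
            {
                "scaffold": scaf,
                "start": track.breaks[:-1].astype(int),
                "end": track.breaks[1:].astype(int),
                "rate": track.rates,
            }
        )
        io.write_bedgraph(out / f"truth_{name}.bedgraph", df, "rate")

    print(f"scaffold: {scaf} ({spec.lengths[0]:,} bp), demography: {model.name}")
    print(f"substitutions: {subs.total():,} (target mean divergence 0.043)")
    print(f"SNP panel: {panel.n_sites:,} segregating sites in {panel.n_hap} haplotypes")
    print(f"exons: {annots.get(scaf).shape[0]} intervals, {annots.total_bp():,} bp")
    print(f"motifs: {motifs.total()} (8x enrichment toward high-recombination windows)")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
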