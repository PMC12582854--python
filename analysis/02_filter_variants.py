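"""Apply the post-genotyping SNP filters to the synthetic panel.

Removes SNP clusters (>= 3 SNPs in 10 bp) and heterozygote-excess sites
(exact Hardy-Weinberg p < 0.01) and writes the filtered VCF.
"""

from _common import RESULTS, simulated_inputs
from ratemaps import io
from ratemaps.variants import PolymorphismSet, filter_hwe, filter_snp_clusters


def main() -> None:
    out = RESULTS / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    *_, panel, _, _ = simulated_inputs()
    snps = PolymorphismSet.from_panel(panel)
    n0 = snps.n_sites
    snps, n_cluster = filter_snp_clusters(snps, k=3, w=10)
    snps, n_hwe = filter_hwe(snps, p_threshold=0.01)
    io.write_vcf(out / "panel.filtered.vcf", snps)
    print(f"input SNPs: {n0:,}")
    print(f"removed by cluster filter (>=3 in 10 bp): {n_cluster}")
    print(f"removed by heterozygote-excess filter (p < 0.01): {n_hwe}")
    print(f"surviving SNPs: {snps.n_sites:,} -> {out / 'panel.filtered.vcf'}")


if __name__ == "__main__":
    main()
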