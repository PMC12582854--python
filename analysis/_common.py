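"""Shared configuration for the numbered analysis drivers.

Each driver regenerates the synthetic inputs deterministically from SEED,
so the scripts can be run independently or in order; outputs land under
results/.
"""

from pathlib import Path

import numpy as np

from ratemaps.demography import bottleneck_decline
from ratemaps.genome import GenomeSpec, TrueRateTrack
from ratemaps.synthdata import (
    place_motifs,
    simulate_annotations,
    simulate_haplotypes,
    simulate_substitutions,
)

SEED = 20_250_901
RESULTS = Path(__file__).resolve().parent.parent / "results"

# study-condition constants
SCAFFOLD_LENGTH = 4_000_000
MEAN_DIVERGENCE = 0.043
BRANCH_GENS = 54.9e6 / 5.0  # divergence time over generation time
MU_TRUE = MEAN_DIVERGENCE / BRANCH_GENS
MU_CONVERSION = 0.4e-8
REC_RATE_CM_MB = 0.85
N_DIPLOIDS = 5


def genome():
    return GenomeSpec.single(SCAFFOLD_LENGTH, gc=0.41)


def truth_tracks():
    spec = genome()
    scaf = spec.names[0]
    rng = np.random.default_rng(SEED)
    k = 40
    bounds = np.linspace(0, SCAFFOLD_LENGTH, k + 1)
    mu_rates = MU_TRUE * np.exp(rng.normal(-0.25**2 / 2, 0.25, size=k))
    rec_rates = REC_RATE_CM_MB * 1e-8 * np.exp(rng.normal(-0.5**2 / 2, 0.5, size=k))
    return (
        TrueRateTrack(scaf, bounds, mu_rates),
        TrueRateTrack(scaf, bounds, rec_rates),
    )


def simulated_inputs():
    """Regenerate all synthetic inputs (deterministic in SEED)."""
    spec = genome()
    mu_track, rec_track = truth_tracks()
    model = bottleneck_decline()
    subs = simulate_substitutions(spec, mu_track, BRANCH_GENS, seed=SEED)
    panel = simulate_haplotypes(
        model, MU_CONVERSION, rec_track, 2 * N_DIPLOIDS, SCAFFOLD_LENGTH, seed=SEED + 1
    )
    annots = simulate_annotations(spec, 0.05, 1500, seed=SEED + 2)
    motifs = place_motifs(spec, rec_track, enrichment=8.0, n_motifs=80, seed=SEED + 3)
    return spec, model, mu_track, rec_track, subs, panel, annots, motifs
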