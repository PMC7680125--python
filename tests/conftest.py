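import numpy as np
import pandas as pd
import pytest

from nucshift import calling, dyads, shifts, synth


@pytest.fixture(scope="session")
def small_genome():
    return synth.make_genome(1, 100_000, 20, min_gene_length=1000, seed=7)


@pytest.fixture(scope="session")
def shifted_run():
    """A modest end-to-end run with +2/+3/+4 displaced 10 bp downstream."""
    genome = synth.make_genome(1, 200_000, 50, min_gene_length=1000, seed=3)
    truth_a = synth.place_nucleosomes(genome, n_per_gene=5)
    truth_b = synth.apply_shifts(truth_a, {2: 10, 3: 10, 4: 10}, genome, condition="mut")
    frags_a = synth.simulate_fragments(truth_a, genome, 300, seed=31)
    frags_b = synth.simulate_fragments(truth_b, genome, 300, seed=32)
    dy_a = dyads.fragments_to_dyads(frags_a)
    dy_b = dyads.fragments_to_dyads(frags_b)
    track_a = dyads.build_track(dy_a, genome)
    track_b = dyads.build_track(dy_b, genome)
    calls_a = calling.call_nucleosomes(calling.smooth_track(track_a), dy_a)
    calls_b = calling.call_nucleosomes(calling.smooth_track(track_b), dy_b)
    results = shifts.run_shift_analysis(calls_a, calls_b, genome)
    return {
        "genome": genome,
        "truth_a": truth_a,
        "truth_b": truth_b,
        "dyads_a": dy_a,
        "dyads_b": dy_b,
        "track_a": track_a,
        "track_b": track_b,
        "calls_a": calls_a,
        "calls_b": calls_b,
        "results": results,
    }


def make_calls(dyad_positions, chrom="chr1", sd=10.0, occ=100):
    """Minimal call table for matching/testing units."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "dyad": np.asarray(dyad_positions, dtype=int),
            "dyad_sd": sd,
            "occupancy": occ,
            "score": 1.0,
            "dyad_mean": np.asarray(dyad_positions, dtype=float),
            "untestable": False,
        }
    )
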