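import numpy as np
import pytest

from srnacall.coverage import Contig, CoverageTrack
from srnacall.simulate import SimulationConfig, simulate_dataset
from srnacall.types import SAMPLE_S1, SAMPLE_S2, Genome, Replicon


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(replicon_lengths=(120_000, 60_000), n_genes=70,
                           n_transcripts=40, rng_seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across tests (read-only)."""
    return simulate_dataset(small_config(seed=7))


def track_from_depth(depth, starts5=None, ends3=None, strand="+",
                     sample=SAMPLE_S1, replicon="chr") -> CoverageTrack:
    """Coverage track with explicitly given per-position arrays."""
    depth = np.asarray(depth, dtype=np.int64)
    genome = Genome([Replicon(replicon, "A" * len(depth))])
    track = CoverageTrack(genome)
    tr = track._get(replicon, strand, sample)
    tr["depth"][:] = depth
    if starts5 is not None:
        tr["starts5"][:] = np.asarray(starts5, dtype=np.int64)
    if ends3 is not None:
        tr["ends3"][:] = np.asarray(ends3, dtype=np.int64)
    return track


def make_contig(start, end, strand="+", replicon="chr", contig_id="RC00001",
                mean_depth=20.0, **kw) -> Contig:
    return Contig(contig_id, replicon, strand, start, end, mean_depth,
                  kw.pop("per_sample_depth", {SAMPLE_S1: mean_depth / 2,
                                              SAMPLE_S2: mean_depth / 2}),
                  kw.pop("seed_start", start), kw.pop("seed_end", end),
                  kw.pop("over_length", False))
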