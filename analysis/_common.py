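"""Shared paths and the deterministic fixture build for the analysis scripts.

Genome-scale files live under scratch/ (regenerated on demand, seed 1);
result tables go under results/.
"""

from pathlib import Path

from tamine.synth import GenomeSpec, make_genome, make_hit_table

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "synthetic_genome"
RESULTS = ROOT / "results"

SEED = 1
# Study conditions: two replicons (chromosome + mega-plasmid scale ratio),
# five planted TA pairs including the -8 nt overlap geometry, 50 decoys.
SPEC = GenomeSpec(seed=SEED, fixed_distances=(-8, 0, 10, -1, 30))


def fixture_paths():
    """Generate (or reuse) the seed-1 synthetic genome and hit table."""
    RESULTS.mkdir(exist_ok=True)
    genbank = SCRATCH / "genome.gbk"
    hit_table = SCRATCH / "hits.domtblout"
    paths, truth = make_genome(SPEC, SCRATCH)
    make_hit_table(truth, hit_table, seed=SEED)
    return paths, truth, hit_table
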