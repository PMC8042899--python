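#!/usr/bin/env python
"""Generate the study-like synthetic panel.

Three diverged duck-like populations (19 wild, 25 Chinese-domestic, 21
Southeast/South-Asian) plus 4 deep-outgroup samples on two 2-Mb
chromosomes, with a 400-kb SEASA->DomCN introgressed tract planted on
chr1 (half the recipient haplotypes) and a 200-kb sweep region planted in
DomCN on chr2. The multi-megabyte VCF and its companions are scratch
artifacts, regenerated on demand: they go under scratch/fixture/.
"""

import sys
from pathlib import Path

from popgenscan.synth import (IntrogressionPlant, ScenarioConfig, SweepPlant,
                              generate_fixture, write_fixture)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "fixture"

cfg = ScenarioConfig(
    chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
    locus_bp=10_000, model_name="M1", seed=SEED,
    introgression=IntrogressionPlant("SEASA", "DomCN", "chr1",
                                     800_001, 1_200_000, fraction=0.5),
    sweep=SweepPlant("DomCN", "chr2", 500_001, 700_000))

fx = generate_fixture(cfg)
paths = write_fixture(fx, OUT)
print(f"samples: {fx.vt.n_samples}; SNPs: {fx.vt.n_sites}")
print(f"planted tract:  chr1:800,001-1,200,000 (donor SEASA, fraction 0.5)")
print(f"planted sweep:  chr2:500,001-700,000 (DomCN homogenized)")
for k, v in paths.items():
    print(f"  {k}: {v}")
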