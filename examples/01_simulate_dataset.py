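"""Simulate a pseudo-haploid dataset with known truth and write it to disk.

The default world has an outgroup on a long branch, three moderately
drifted source populations and a target admixed 0.48/0.33/0.19 across them.
Genotypes are observed pseudo-haploid: one sampled allele per site with
configurable missingness and error.
"""

import tempfile
from pathlib import Path

from paleopop import genio, simdata

config = simdata.SimConfig(n_snps=5000, seed=1, missingness=0.8)
world = simdata.simulate_world(simdata.default_world_specs(), config)

out = Path(tempfile.mkdtemp()) / "toy"
simdata.emit_dataset(world, out)

matrix, ind = genio.read_eigenstrat(out)
print(f"wrote {out}.geno/.snp/.ind + metadata + truth")
print(f"{matrix.n_individuals} individuals x {matrix.n_snps} SNPs")
called = (matrix.calls >= 0).mean()
print(f"callable fraction {called:.3f} (missingness target was 0.8)")
print("ancestry truth for one target individual:",
      world.truth["ancestry"]["target_0"])
# Every downstream example rebuilds data like this, so no downloads or
# binary fixtures are ever needed.
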