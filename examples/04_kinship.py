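"""Pairwise kinship from pseudo-haploid mismatch rates.

Plants an identical pair and first/second/third-degree relatives in a
sample of unrelated individuals, then estimates theta = 1 - normalized P0
from 1-Mb windowed mismatch rates and classifies each pair.
"""

from paleopop import kinrel, simdata

world, ids = simdata.kinship_study_world(seed=4, n_snps=10_000)
matrix = world.matrix.take_individuals(ids)
estimates = kinrel.kinship_all_pairs(matrix)

truth = {frozenset((r["id1"], r["id2"])): r for r in world.truth["relations"]}
print(f"{'pair':22s} {'theta':>7s} {'+/-':>6s} {'degree':>12s} {'truth':>10s}")
for e in estimates:
    key = frozenset(e.pair)
    if key in truth or e.degree not in ("unrelated", "insufficient-data"):
        t = truth.get(key)
        print(f"{'-'.join(e.pair):22s} {e.theta:7.3f} {e.se:6.3f} "
              f"{e.degree:>12s} {(t['relation'] if t else '-'):>10s}")

groups = kinrel.detect_identicals(estimates)
print("\nidentical groups to merge:", groups)
merged, report = kinrel.merge_individuals(matrix, groups[0])
print(f"merged into {report['merged_id']}: conflict rate at co-called sites "
      f"= {report['conflict_rate']:.3f} (haploid draws from heterozygous "
      "sites disagree about half the time)")
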