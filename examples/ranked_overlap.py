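"""Permutation test for the overlap of two ordered gene lists.

Generates two rankings with planted correlation 0.6 (think: a resistant cell
line's differential-expression signature vs post-treatment patient biopsies)
and asks whether their top-100 sets share more genes than chance.
"""

from isoflux.ranklist import ordered_overlap_test
from isoflux.synthdata import ScenarioSpec, make_ranked_pair

list_a, list_b, sidecar = make_ranked_pair(ScenarioSpec(seed=5, rho=0.6, n_genes=1000))
result = ordered_overlap_test(list_a, list_b, depths=[50, 100, 200], n_perm=1000, seed=5)

for depth, obs, null_mean, p in zip(
    result.depths, result.observed, result.null_mean, result.p_values
):
    print(f"depth {depth:4d}: observed overlap {obs:5.0f}, null mean {null_mean:6.2f}, p={p:.4g}")
# Under independence the expected overlap at depth n is n^2/N; the observed
# overlaps sit far above the shuffled null at every depth, so the two
# signatures share ordering far beyond chance.
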