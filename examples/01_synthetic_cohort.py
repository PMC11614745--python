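"""Generate a synthetic brainstem-cortex cohort and inspect its ground truth.

The generator plants a dominant global coupling factor, K brainstem
communities with distinct cortical projection maps, a unimodal-transmodal
cortical axis, and receptor/term annotation maps that are known mixtures of
the projection maps.
"""

import numpy as np

from stemfc import generate_cohort

cohort = generate_cohort(n_subjects=4, n_cortex=100, n_brainstem=20,
                         k_communities=3, n_timepoints=210, seed=1)

truth = cohort.truth
sizes = np.bincount(truth.community_of_brainstem_node)[1:]
print(f"subjects: {len(cohort.subjects)}, nodes: {cohort.n_cortex} cortical "
      f"+ {cohort.n_brainstem} brainstem, timepoints: "
      f"{cohort.subjects[0].n_timepoints} at dt = {cohort.subjects[0].dt} s")
print(f"planted community sizes: {sizes.tolist()}")
print(f"receptor maps: {cohort.receptor_maps.shape[1]}, "
      f"term maps: {cohort.term_maps.shape[1]}")
for k in range(len(sizes)):
    m = truth.dominant_receptor_per_community[k]
    print(f"  community {k + 1}: dominant receptor = "
          f"{cohort.receptor_maps.columns[m]} "
          f"(|beta| = {abs(truth.receptor_coefficients[m, k]):.2f})")
# The community sizes and dominant receptors above are the ground truth that
# the downstream examples try to recover from the raw time series alone.
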