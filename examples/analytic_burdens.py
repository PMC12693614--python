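"""Closed-form mutation burdens of a single tree crown.

A depth-5 crown (32 terminal branches), 3 apical stem cells per meristem
layer, a 0.4 Gbp haploid genome mutating at 5e-10 per base per year, grown
for 25 years under uniform time allocation.
"""

from crownburden import (
    MutationParams,
    allocate_time,
    burden_expectations,
    make_crown,
    sampling_profile,
)

topo = make_crown(5)
alloc = allocate_time(topo, tilt=0.0, total_time=25.0)
params = MutationParams(genome_size=4e8, mu=5e-10, asc_count=3)

print(sampling_profile(topo, params.asc_count).to_string(index=False))
print()

exp = burden_expectations(params, topo, alloc)
print(f"expected per-tip burden:      {exp.per_tip:.3f}")
print(f"expected total (all tips):    {exp.crown_tips:.3f}")
print(f"expected unique (crown-wide): {exp.crown_unique:.3f}")
print()
print(
    "Each sequenced fruit or leaf carries ~2*G*mu*T mutations regardless of"
    " architecture; the unique count across the whole crown is the"
    " architecture-sensitive quantity."
)
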