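"""Non-synonymous position map and cross-group sharing summary.

Plants 12 shared non-synonymous positions into a 4-group family and shows
that the variability map recovers exactly those as shared by all groups.
"""

from rlkscan import nonsyn_position_map, shared_position_summary
from rlkscan.simulate import SimConfig, simulate_family

planted = (3, 7, 18, 25, 40, 60, 75, 110, 130, 138, 155, 160)
sim = simulate_family(SimConfig(
    n_groups=4, members_per_group=4, seed=10,
    between_group_branch=0.0, within_group_branch=0.0,
    planted_shared_nonsyn=planted,
))

vt = nonsyn_position_map(sim.alignment, sim.groups)
summary = shared_position_summary(vt)
print(f"positions analysed: {summary['n_positions_analysed']}")
print(f"non-synonymously variable: {summary['n_variable']}")
print(f"shared by 2+ groups: {summary['n_shared_2plus']}, "
      f"by all groups: {summary['n_shared_all']}")
recovered = sorted(p.position + 1 for p in vt.positions
                   if p.shared_class == "shared_all")
print("shared-by-all positions (1-based):", recovered)
# With zero divergence the only variation is the planted set, so the
# map recovers exactly the 12 planted positions as shared by all groups.
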