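"""Assemble a force of infection mechanistically from its components.

The net FOI for the focal host is the sum over host species of
contact rate x transmission success x infestation prevalence. This script
builds each component from the laboratory-scale models: a Holling Type II
contact rate at field densities, the per-contact transmission success
implied by the dispersal experiments, and a field prevalence.
"""

from foidecomp import FOIComponents, HollingParams, foi_from_components, holling_mean_contacts

MINUTES_PER_DAY = 60 * 24

# contact rates per day at a density of 10 partner snails per 0.1 m^2,
# using the fitted encounter rate and handling time
params = HollingParams(encounter_rate=0.012, handling_time=3.25)
contacts_per_day = holling_mean_contacts(params, density=10, obs_minutes=MINUTES_PER_DAY)

# per-contact transmission success: high within species, low between species
intra = FOIComponents(contact_rate=contacts_per_day, success_prob=0.32, prevalence=0.5)
inter = FOIComponents(contact_rate=contacts_per_day, success_prob=0.03, prevalence=0.5)

print(f"contacts per snail per day at density 10: {contacts_per_day:.1f}")
print(f"intraspecific FOI contribution: {foi_from_components([intra]):.2f} / day")
print(f"interspecific FOI contribution: {foi_from_components([inter]):.2f} / day")
print(f"combined FOI: {foi_from_components([intra, inter]):.2f} / day")
print(
    "\nWith identical contact rates and prevalence, the order-of-magnitude gap "
    "between the two contributions comes entirely from transmission success — "
    "the host-preference barrier, not a lack of encounters."
)
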