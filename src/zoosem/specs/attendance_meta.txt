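# A priori attendance meta-model: the theory-derived superset of admissible
# pathways. The stepwise search prunes unsupported edges and may re-add
# whitelisted ones; it never invents edges outside this file.
attendance ~ total_animals + pop_10km + body_mass + gdp + dissimilarity + mammal_richness + species_richness + area + threatened_prop + national_population
total_animals ~ species_richness + area + gdp + body_mass + mammal_richness
species_richness ~ mammal_richness + area + body_mass + gdp
dissimilarity ~ area + body_mass + species_richness
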