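# Functional-role map for the genome-scale Synechocystis reconstruction.
#
# The scenario layer is model-agnostic: it addresses reactions only through
# this table.  Replace each placeholder with the corresponding reaction id
# from data/external/synechocystis_core_s1.xml before running the
# genome-scale acceptance checks.  The synthetic core network ships its own
# table (cyanoflux.synth.core_model_roles) with the same keys.

photon_exchange: FILL_IN        # photon uptake exchange
bicarbonate_exchange: FILL_IN
co2_exchange: FILL_IN
o2_exchange: FILL_IN
acetate_exchange: FILL_IN
psii: FILL_IN                   # PSII water-splitting O2 evolution
psi: FILL_IN
oxidase: FILL_IN                # terminal (cytochrome c) oxidase
mehler_like: FILL_IN            # flavodiiron NADPH:O2 (no ROS)
ros_psii: FILL_IN               # superoxide formation at PSII
ros_psi: FILL_IN                # superoxide formation at PSI
carboxylase: FILL_IN            # RuBisCO carboxylase
oxygenase: FILL_IN              # RuBisCO oxygenase
biomass: FILL_IN                # biomass objective pseudo-reaction
atp_maintenance: FILL_IN
glycogen_sink: FILL_IN
glycogen_source: FILL_IN
glycogen_synthesis: FILL_IN
glycogen_degradation: FILL_IN
transhydrogenase: FILL_IN
ndh1_nadh: FILL_IN              # NADH-accepting NDH-1 mode, if modeled
opp: FILL_IN                    # committed OPP step (G6P dehydrogenase)
gdh: FILL_IN                    # glutamate dehydrogenase
pgk: FILL_IN                    # phosphoglycerate kinase
pgam: FILL_IN                   # phosphoglycerate mutase
pgm: FILL_IN                    # phosphoglucomutase
glycine_route: FILL_IN          # glyoxylate -> glycine aminotransferase
glycerate_route: FILL_IN        # glyoxylate -> glycerate re-entry
proline_degradation: FILL_IN
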