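# External datasets (not bundled)

The two genome-scale checks in `tests/test_acceptance.py` run against the
published core reconstruction of *Synechocystis* sp. PCC 6803, distributed
as journal supplementary material (an annotated SBML file, several MB).
It is not redistributable inside this repository; to enable those checks,
place a copy here as:

    data/external/synechocystis_core_s1.xml

and fill in `roles_dataset_s1.yaml` (same directory) with that file's
reaction identifiers for each functional role.  Without the file the two
tests fail with a message pointing here; everything else in the test suite
runs on the synthetic core network and needs no external data.
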