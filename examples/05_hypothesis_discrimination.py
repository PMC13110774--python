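"""Full chain: synthetic in vitro scenario to binding-site assignment.

Generates a dimer population in which one ligand occupies a catalytic site
and the second the secondary site of the *other* monomer (the "cross"
pairing at 2.5 nm), measures it, and asks which of three pairing
hypotheses the recovered distance distribution supports.
"""

import json
import tempfile

import dimerdeer as dd

with tempfile.TemporaryDirectory() as workdir:
    bundle = dd.generate_scenario(dd.invitro_config())
    dd.write_bundle(bundle, workdir)
    report = dd.run_pipeline(workdir)

print(f"recovered peak: {report.inversion['modal_distance_nm']:.3f} nm, "
      f"reliable up to {report.inversion['reliability_limit_nm']:.1f} nm")
print("hypothesis ranking (overlap with recovered P(r)):")
for name, score, call in report.ranking:
    print(f"  {name:16s} score = {score:.3f}  -> {call}")
print(f"occupancy: f0/f1/f2 = {report.occupancy['f0']:.2f}/"
      f"{report.occupancy['f1']:.2f}/{report.occupancy['f2']:.2f}, "
      f"cooperativity: {report.cooperativity['verdict']}")
print(f"CW free-ligand fraction: {report.cw['free_fraction']:.3f}")
# The 4.1 nm both-catalytic pairing is excluded outright and the 3.0 nm
# intra-monomer pairing falls short of consistency: only the cross pairing
# reproduces the measured 2.5 nm distance.
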