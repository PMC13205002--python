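"""Score two configurations for the same subject and compare components.

PCS = w_neuro * u_pattern * ln(1 + E_focus): activation weight times
descriptor balance times log-compressed focusing.  A drop in any factor
drops the composite score.
"""

from etrec import ElectrodeConfig, SimulationPipeline, SubjectDescriptors

subject = SubjectDescriptors(sex=0, age=22, height_cm=165, weight_kg=55, subject_id="demo")
pipe = SimulationPipeline()

print(f"{'config':<10}{'E_focus':>10}{'w_neuro':>9}{'u_pattern':>11}{'PCS':>8}")
for cfg in (ElectrodeConfig(2.0, 0.5), ElectrodeConfig(4.5, 3.0)):
    c = pipe.features(subject, cfg).pcs
    print(f"{cfg.label:<10}{c.e_focus:>10.1f}{c.w_neuro:>9.3f}{c.u_pattern:>11.3f}{c.pcs:>8.3f}")
print("\nhigher PCS = better expected spatial discriminability for this subject")
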