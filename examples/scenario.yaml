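# Weekly combined therapy for a strong-antigenicity patient.
params: {preset: section4, beta: 0.1}
schedule: {d_cd4: 10, d_il4: 80, tau: 7}
initial_conditions: [[0.1, 0.01, 0]]
horizon: 140
policy: {rtol: 1.0e-9, atol: 1.0e-12}
output: {directory: out, format: csv}
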