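# Second-order autoregulation model parameters, one row per ARI grade.
# Transcribed from the original publication of the model
# (Tiecks et al., Stroke 1995;26:1014-1019, Table 1):
#   T = time constant (s), D = damping factor, K = autoregulatory gain.
# ARI 0 (K = 0) disables feedback entirely; ARI 9 is the fastest,
# most complete recovery. Do not edit: the loader checks a sha256
# of this file against the value recorded in cadenza.tiecks.
ari,T,D,K
0,2.00,0.00,0.00
1,2.00,1.60,0.20
2,2.00,1.50,0.40
3,2.00,1.15,0.60
4,2.00,0.90,0.80
5,1.90,0.75,0.90
6,1.60,0.65,0.94
7,1.20,0.55,0.96
8,0.87,0.52,0.97
9,0.65,0.50,0.98
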