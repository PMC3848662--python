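# Suicide-substrate (mechanism-based inhibitor) reference run.
# Species order: E, S, X, Y, Ei, P.  Partition ratio r = k3/k4 = 5,
# mu = e0/s0 = 1, so the determining factor (1+r)mu = 6 > 1: substrate
# exhaustion is expected at the final time.  The run horizon T = 12 s is
# chosen so the reaction reaches its post-exhaustion plateau (the substrate
# falls below 1% of s0 around t = 8 s with these rate constants); the
# time-step robustness study uses the shorter T = 4 s horizon.

epsilon = 1.0
fixed_charge = 0.1
phi0 = -80.0

[domain]
a = 2.0
b = 1.0
h = 0.1

[[species]]
name = "enzyme"
d = 1e-3
z = 1
c0 = 0.5

[[species]]
name = "substrate"
d = 2e-3
z = 0
c0 = 0.5

[[species]]
name = "complex_X"
d = 5e-3
z = 1
c0 = 0.0

[[species]]
name = "complex_Y"
d = 1e-3
z = 1
c0 = 0.0

[[species]]
name = "inactive_enzyme"
d = 2e-3
z = 1
c0 = 0.0

[[species]]
name = "product"
d = 4e-6
z = 0
c0 = 0.0

[model]
preset = "suicide"

[model.constants]
k1 = 2.0
km1 = 4.0
k2 = 12.0
k3 = 10.0
k4 = 2.0
e0 = 0.5
s0 = 0.5

[solver]
dt = 1e-2
T = 12.0
eps = 1e-4

[probes]
points = [[0.0, 0.0]]

[output]
directory = "out_suicide"
snapshot_every = 50
formats = ["csv", "vtk"]
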