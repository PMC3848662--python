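# Cooperative (two-binding-site) reference run, positive cooperativity.
# Species order: E, S, X, Y, P.  Only the pseudo-equilibrium constants
# K1 = (km1+k2)/k1 and K2 = (k4+km3)/k3 are prescribed; the first-order
# constants default to 1/s and k1, k3 are derived from K1, K2.

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
name = "product"
d = 4e-6
z = 0
c0 = 0.0

[model]
preset = "cooperative"

[model.constants]
K1 = 1000.0
K2 = 0.001
km1 = 1.0
k2 = 1.0
km3 = 1.0
k4 = 1.0
e0 = 0.5
s0 = 0.5

[solver]
dt = 1e-2
T = 4.0
eps = 1e-4

[probes]
points = [[0.0, 0.0]]

[output]
directory = "out_cooperative"
snapshot_every = 50
formats = ["csv", "vtk"]
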