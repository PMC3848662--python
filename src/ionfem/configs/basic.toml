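# Basic enzyme reaction (Michaelis-Menten QSSA) reference run.
# Elliptical cell a=2, b=1; concentrations in uM, time in s, potential in mV.

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
c0 = 1.0

[[species]]
name = "substrate"
d = 2e-3
z = 0
c0 = 800.0

[[species]]
name = "product"
d = 5e-3
z = 1
c0 = 0.0

[model]
preset = "basic"

[model.constants]
k2 = 1.4e4
k_M = 9e-5
c1_0 = 1.0

[model.units]
k_M = "M"

[solver]
dt = 1e-3
T = 0.2
eps = 1e-4

[probes]
points = [[0.0, 0.0]]

[output]
directory = "out_basic"
snapshot_every = 50
formats = ["csv", "vtk"]
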