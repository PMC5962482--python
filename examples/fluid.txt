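# Commented command-file template: a density-3 water-like DPD fluid.
# All quantities are in reduced DPD units (cutoff = 1, kBT = 1, mass = 1).
# '#' starts a comment anywhere on a line.

[Box]
# box edge lengths; every axis must be at least 3 cutoffs
lengths = 10 10 10
# per-axis boundary mode: periodic | reflective
boundaries = periodic periodic periodic

[ParticleTypes]
# name  [mass]  [charge]      (charge is carried but exerts no force)
W  1.0  0.0

[Interactions]
# typeA typeB a_ij            (symmetric completion is automatic;
# a 'default <value>' line fills any unlisted pair)
W W 25

[Molecules]
# one block per species; inside a block:
#   particles <type> [<type> ...]   fragment sequence of one copy
#   bond i j k r0                   topological harmonic bond
#   backbone i j k r0               backbone bond (same force law)
#   count <n>                       number of copies
#   placement random|lattice
molecule water
    particles W
    count 3000
end

[Simulation]
steps = 2000
dt = 0.04
kBT = 1.0
sigma = 3.0                   # noise amplitude; gamma = sigma^2/(2 kBT)
integrator = GWMVV            # GWMVV | SCMVV | DPDMVV | S1MVV | PNHLN
lambda = 0.65                 # GWMVV velocity-prediction parameter
iterations = 5                # SCMVV self-consistent iterations
coupling = 1.0                # PNHLN control gain
output_every = 100
seed = 2
rng = uniform                 # uniform | gaussian pair noise
gravity = 0 0 0
velocity_scaling = 0          # 0 = off, k = rescale every k steps
minimization_steps = 0        # steepest-descent start relaxation
threads = 1

[Constraints]
# molecule-scoped constraints, e.g.:
#   fixation water position          pin a species in place
#   boundary water 1 4 1 4 1 4       reflective sub-box walls
#   kick water 0.5 0 0 10            force kick every 10 steps
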