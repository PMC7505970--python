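# Default parameters of the soil microbe-enzyme decomposition model.
# All masses in mg carbon, times in hours.  Volume-dependent entries
# (I_C, I_D, K_m, theta) are given at unit soil volume (k = 1); the loader
# rescales them to the system size k below (inputs and K_m scale with k,
# the encounter factor in theta scales with 1/k).
V: 1.0e-9          # cm^3, unit soil volume of one cell
k: 10              # system size: unit volumes (and ~cells) per microsite
L: 10              # lattice side, microsites
phi: 0.5           # enzyme allocation fraction (evolving trait)
gamma_M: 0.3       # microbial growth efficiency
gamma_Z: 0.4       # enzyme carbon production fraction
omega_M: 1.0e-9    # mg, mass of one cell
omega_Z: 1.0e-16   # mg, mass of one enzyme molecule
omega_C: 1.0e-16   # mg, mass of one SOC molecule
omega_D: 1.0e-19   # mg, mass of one DOC molecule
alpha: 1.0e10      # structural cost of one cell (DOC molecules)
alpha_prime: 2.33e10   # energetic cost of one cell
beta: 1.0e3        # structural cost of one SOC molecule
rho: 1.0e3         # structural cost of one enzyme molecule
rho_prime: 1.5e3   # energetic cost of one enzyme molecule
d_M: 2.0e-4        # 1/h, cell death rate
d_Z: 2.0e-3       # 1/h, enzyme deactivation rate
V_max: 0.42        # 1/h, maximum uptake rate
theta: 7.0e5       # 1/(mg h), encounter probability x decomposition rate
K_m: 3.0e-10       # mg, uptake half-saturation
I_C: 5.0e-13       # mg/h, external SOC input
I_D: 0.0           # mg/h, external DOC input
l_C: 1.0e-6        # 1/h, SOC leaching rate
l_D: 1.0e-6        # 1/h, DOC leaching rate
l: 0.0             # leached fraction of dead-cell/enzyme carbon
p: 0.5             # recycled dead-cell fraction flowing to SOC
T_max: 1.0e6       # h, simulation horizon
p_disp: 0.3        # newborn dispersal probability
p_open: 0.01       # micro-disturbance probability
p_mut: 0.0         # mutation probability per division (0.1 in the
                   # single-site evolutionary demo)
sigma_mut: 0.05    # sd of mutation effect, trait units
sigma_diff: 5.0e-6 # DOC diffusion coefficient
# tau_diff: 1.0    # h, diffusion time step; omit for automatic choice
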