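# Default parameter configuration for the leukocyte state-space models.
#
# Every value here can be overridden by passing a config file or keyword
# arguments; nothing in the library hard-codes these numbers.  The "fixed"
# block holds quantities that are held constant during MAP estimation; the
# "*_init" blocks hold the default Nelder-Mead starting values for the free
# parameters, which double as the generating values of the synthetic cohort.

fixed:
  # Shared between TCM / TCM-CRP and the PK submodel of JM.
  k_me: 0.07        # 1/day   cytotoxicity (TGN surrogate) elimination rate;
                    #         gives the multi-week delay to steady-state response
  rho: 4.67         # 1e9/L   feedback scale of the leukopoiesis Hill term;
                    #         the drug-free steady-state count is rho*(k_pl_max/k_L-1)^(1/gamma)
  gamma: 1.0        # -       Hill exponent of the proliferation feedback
  sigma_leuk: 0.057 # -       measurement SD of log leukocyte counts (literature value)
  sigma_crp: 0.1    # -       measurement SD of log(CRP+1) (from ~10% CV at 3.5 mg/L)
  t_dur: 1.0        # day     dose-effect window of the K-PD drug input
  dt: 0.25          # day     Euler-Maruyama / EKF sub-step

tcm_init:
  e_tgn: 0.45       # 1/day   maximal drug-induced cytotoxicity rate
  h: 15.0           # mg/m^2  half-saturation BSA-normalised daily dose
  k_pl_max: 2.0     # 1/day   maximal proliferation rate
  k_L: 1.0          # 1/day   leukocyte elimination rate
  sigma_L: 0.15     # 1/sqrt(day) leukopoiesis diffusion SD

tcm_crp_init:
  theta_ou: 0.15    # 1/day   OU mean-reversion rate of the latent infection level
  sigma_ou: 0.7     # 1/sqrt(day) OU diffusion SD; stationary SD ~ 1.28 on the
                    #         log(CRP+1) scale, sized so that roughly two thirds
                    #         of simulated patients see at least one CRP >= 10 mg/L
  beta_crp: 0.25    # -       volatility coupling: sigma_L(V) = sigma_L0 * exp(beta_crp V)

jm:
  # 3-compartment 6-MP PK + 5-compartment leukopoiesis comparator.
  k_ab: 4.8         # 1/day   gut absorption rate
  k_el: 5.0         # 1/day   plasma elimination rate
  k_cm: 0.75        # amt/day Michaelis-Menten max metabolisation rate (free)
  k: 2.1            # amt     Michaelis constant
  v_cm: 0.12        # -       metabolisation yield into the TGN compartment
  k_me: 0.07        # 1/day   TGN elimination rate
  k_pl_max: 2.0     # 1/day   maximal stem-cell proliferation rate (free)
  gamma: 1.0        # -       feedback exponent (free)
  rho: 4.67         # 1e9/L   feedback scale
  e_max: 0.6        # 1/day   maximal drug effect on stem-cell production (free)
  e_C50: 0.5        # amt     TGN level of half-maximal effect
  k_tr: 0.8         # 1/day   maturation-chain transit rate (free)
  k_L: 1.0          # 1/day   circulating-leukocyte elimination rate (free)
  sigma_leuk: 0.057 # -       log-scale measurement SD (free)

nm_ddof: 1          # delta dof of the naive-mean model's sample variance
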