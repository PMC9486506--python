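"""Screen-style correlation between drug-free growth and drug response.

Generates a gene-deletion-like ensemble of 500 strains with dispersed
drug-free growth rates. Each strain's growth under drug follows the
feedback fixed point — slower strains express more drug target and are
proportionally less inhibited. Spearman's rho (with a seeded bootstrap SE)
between drug-free growth and normalized response quantifies the feedback.
"""

import growthfeedback as gf
from growthfeedback.synthetic_data import generate_mutant_ensemble

cfg = gf.default_synth_config(seed=1)

for label, feedback in [("feedback intact (wild-type)", "wildtype"),
                        ("feedback cut (constant expression)", "constant")]:
    strains = gf.screen_responses(generate_mutant_ensemble(cfg, feedback=feedback))
    res = gf.spearman_bootstrap(strains["g0"].to_numpy(),
                                strains["response"].to_numpy(),
                                n_boot=1000, seed=1)
    print(f"{label}:")
    print(f"  rho_s = {res.rho_s:+.3f} +/- {res.bootstrap_se:.3f} "
          f"(n = {res.n_strains}, 95% CI {res.ci95[0]:+.3f}..{res.ci95[1]:+.3f})")
# With the loop intact, slower-growing strains respond less to the drug
# (significantly negative rho); with expression pinned, the responses carry
# no information about the drug-free growth rate and rho is near zero.
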