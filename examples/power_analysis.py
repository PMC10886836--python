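"""Prospective sample sizes for a within-subject emotion study.

Inverts the noncentral-t and noncentral-F power functions: how many
participants are needed for a paired t-test at a medium effect
(d_z = 0.5) and for a 3-condition repeated-measures ANOVA at f = 0.25,
both at alpha = 0.05 and 80% power?
"""

from mstate import (power_paired_t, power_rm_anova, required_n_paired_t,
                    required_n_rm_anova)

n_t = required_n_paired_t(d=0.5, alpha=0.05, power=0.8, two_sided=True)
n_f = required_n_rm_anova(f=0.25, alpha=0.05, power=0.8, m=3, rho=0.5, eps=1.0)

print(f"paired t-test (d=0.5, two-sided, alpha=0.05, power 0.8): n = {n_t}")
print(f"  power at n     = {power_paired_t(n_t, 0.5):.4f}")
print(f"  power at n - 1 = {power_paired_t(n_t - 1, 0.5):.4f}")
print(f"RM-ANOVA within (f=0.25, m=3, rho=0.5, eps=1):          N = {n_f}")
print(f"  power at N     = {power_rm_anova(n_f, 0.25, 3):.4f}")
print(f"  power at N - 1 = {power_rm_anova(n_f - 1, 0.25, 3):.4f}")
print("The returned sizes are the smallest reaching the target power;")
print("one participant fewer falls below 0.8 in both designs.")
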