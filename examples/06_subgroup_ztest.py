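"""Two-sided z-test for subgroup differences from published-style estimates.

Standard errors are recovered from printed 95% CI limits as
(ln hi - ln lo)/3.92, then z = (theta1 - theta2)/sqrt(se1^2 + se2^2). The
two worked pairs are male/female ORs for disease and male/female HRs for
all-cause mortality: the first difference is significant, the second is not.
"""

from mrdose.linear import estimate_from_ci, subgroup_difference_z

male_or = estimate_from_ci(1.81, 1.70, 1.92)
female_or = estimate_from_ci(1.43, 1.32, 1.55)
z, p = subgroup_difference_z(male_or, female_or)
print(f"disease OR 1.81 (1.70-1.92) vs 1.43 (1.32-1.55): z = {z:.2f}, p = {p:.1e}")

male_hr = estimate_from_ci(1.14, 1.08, 1.21, scale="logHR")
female_hr = estimate_from_ci(1.07, 1.00, 1.15, scale="logHR")
z, p = subgroup_difference_z(male_hr, female_hr)
print(f"all-cause HR 1.14 (1.08-1.21) vs 1.07 (1.00-1.15): z = {z:.2f}, p = {p:.2f}")
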