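"""The K-L lines implied by each experimental condition's phase coherence.

For every age x photoperiod condition, the measured pair of subpopulation
order parameters (r1 medial, r2 lateral) fixes a straight line of admissible
(K, L) couplings per community: K_c = -(r_other/r_c) L_c + C_c/r_c with
V(C_c) = r_c. The data determine the line, not a point on it.
"""

from scnsync.two_community import SCN_ORDER_PARAMETERS, all_condition_lines

lines = all_condition_lines()
for cond in ("young_LP", "young_SP", "old_LP", "old_SP"):
    ln = lines[cond]
    r1, r2 = SCN_ORDER_PARAMETERS[cond]
    print(f"{cond:9s} (r1={r1:.2f}, r2={r2:.2f}):")
    print(f"  medial : K1 = {ln.slope1:+.3f} L1 + {ln.intercept1:.3f}")
    print(f"  lateral: K2 = {ln.slope2:+.3f} L2 + {ln.intercept2:.3f}")
print("Higher coherence (SP) pushes the intercept up: stronger within-")
print("community coupling is needed for the same between-community input.")
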