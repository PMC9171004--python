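"""Test one SNP for post-admixture frequency change.

Uses illustrative frequencies for the classic European skin-pigmentation
variant rs1426654 (SLC24A5): derived-allele frequency 0.89 in an early
Central-European farming population whose ancestry is a mix of an Anatolian
farmer source (frequency 1.0) and a western hunter-gatherer source (0.47).
"""

from admixscan import estimate_gamma, site_lrt

f_t, f_s1, f_s2 = 0.89, 1.0, 0.47
gamma = estimate_gamma(f_t, f_s1, f_s2)
print(f"best-fitting source-1 ancestry proportion at this locus: {gamma:.4f}")

# the same target frequency observed as 89 derived alleles out of 100 calls
res = site_lrt(x_t=89, n_t=100, f_s1=f_s1, f_s2=f_s2).iloc[0]
print(f"constrained mixture frequency f_hat = {res['f_hat_t']:.4f}")
print(f"likelihood-ratio statistic       Lambda = {res['lambda']:.4f}")
print(f"chi2(2) p-value                  p = {res['p_value']:.4g}")

# Reading: gamma is the per-site least-squares admixture proportion. Because
# 0.89 lies inside the interval spanned by the two source frequencies, the
# mixture model explains the observation perfectly (Lambda = 0, p = 1):
# the frequency needs no selection to be explained at this single locus.
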