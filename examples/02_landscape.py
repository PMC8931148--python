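"""Compare FrCas9 and SpCas9 target landscapes on one genome.

Coverage is the fraction of positions under at least one protospacer; mean
spacing is the average cut-to-cut distance. On a circular record the mean
spacing is exactly L / (number of sites). A TA-rich PAM tiles an AT-biased
genome far more densely than NGG does.
"""

from pamscape import (
    dinucleotide_spacing,
    find_pam_sites,
    random_genome,
    site_spacing,
    target_coverage,
)

genome = random_genome(10_000, gc=0.4, circular=True, seed=7, record_id="viral-like")

for label, motif, spacer in (("FrCas9", "NNTA", 22), ("SpCas9", "NGG", 20)):
    sites = find_pam_sites(genome, motif, spacer)
    cov = target_coverage(sites, genome)
    spacing = site_spacing(sites, genome)
    print(f"{label} ({motif}, {spacer} nt spacer): "
          f"{len(sites)} sites, coverage {100 * cov.fraction:.2f}%, "
          f"mean spacing {spacing.mean:.2f} bp")

# Raw dinucleotide anchor landscapes (both-strand convention: a palindromic
# TA contributes two coincident anchors, one per orientation).
for word in ("TA", "GG"):
    summary = dinucleotide_spacing(genome, word, count_both_strands=True)
    print(f"5'-{word}-3' anchors: {summary.n_sites}, "
          f"mean spacing {summary.mean:.2f} bp")
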