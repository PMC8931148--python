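"""Enumerate FrCas9 target sites and back-to-back guide pairs.

Builds a small synthetic genome, scans both strands for 5'-NNTA-3' PAMs with
a 22-nt protospacer, and pairs the divergent sites that share a TA anchor.
"""

from pamscape import find_back_to_back_pairs, find_pam_sites, random_genome

genome = random_genome(2000, gc=0.45, circular=True, seed=42, record_id="demo")
sites = find_pam_sites(genome, "NNTA", spacer_len=22)
pairs = find_back_to_back_pairs(sites, "NNTA")

print(f"genome: {len(genome.seq)} bp circular, GC target 0.45")
print(f"sites found: {len(sites)} ({sum(s.strand == '+' for s in sites)} plus-strand)")
print(f"back-to-back pairs: {len(pairs)}, every protospacer gap = "
      f"{set(p.protospacer_gap for p in pairs)}")
first = sites[0]
print(f"first site: {first.site_id} protospacer {first.protospacer} "
      f"PAM {first.pam_seq} cut at {first.cut_pos}")

# Because the TA core is palindromic, every plus-strand site has a minus-
# strand partner six bp away whenever both flanks fit a full protospacer —
# the pair count therefore equals the number of flank-qualified TA loci.
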