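"""Read-length dependence of cross-mapping false positives.

Simulates paired-end reads from a source genome that shares a single 100 bp
segment with an unrelated reference, pseudo-maps them (a read maps if it
shares one 31-mer with the reference), and applies the standard detection
thresholds (coverage >= 0.1, observed/expected coverage >= 0.3, >= 10
mapped reads).  Longer reads claim more collateral coverage per matched
31-mer, so the false-positive rate rises with read length.
"""

from phagenet import false_positive_rates

rates = false_positive_rates(read_lengths=(100, 250), n_replicates=10, seed=0)
for read_len, rate in rates.items():
    print(f"read length {read_len:3d} bp: false-positive detection rate "
          f"{100 * rate:.0f}% over 10 replicates")
print()
print("The same shared segment that stays below the detection thresholds with")
print("100 bp reads is falsely called present with 250 bp reads — shorter")
print("reads are safer for presence calls from pseudo-alignment.")
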