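"""LD-decay and chromosome-segment theory for a small population.

Prints, for Ne = 60: the expected pairwise LD E(r2) = 1/(4cNe+1) at
symmetric intervals of 0.5-18 Stam segments around a causal variant (a
Stam segment is 1/(4Ne) Morgan), the fraction of the variant's variance
captured inside each interval, and the physical size of the 8-segment
(80%-of-variance) window for cattle-, pig- and human-like parameters.
"""

from qtnprofile import decay_table, n_segments, species_window_table, stam_segment_size

NE = 60
print(f"Ne = {NE}: Stam segment = {stam_segment_size(NE):.5f} Morgan "
      f"({stam_segment_size(NE) * 100:.3f} cM); "
      f"expected segments on a 10-Morgan genome = {n_segments(NE, 10):.0f}")
print()
tab = decay_table(NE)
print(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print("interval_segments=2 -> half the QTN variance inside the interval;")
print("8 segments (+-1/Ne Morgan) -> 80%.")
print()
win = species_window_table(width_segments=8)
print(win.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print("window_bp: physical width of the 8-segment window on a 30-Morgan,")
print("3-Gb genome - about 2 Mb for cattle (Ne 100), 5 Mb for pigs and")
print("chickens (Ne 40), 20 kb for humans (Ne 10,000).")
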