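"""Extended length and extension ratio of the straightened myomesin dimer.

The C-terminal myomesin filament My9-(My13)2-My9' rests at ~340-360 A.
When its eight alpha-helical linkers unfold into extended polypeptide
(3.8 A per residue) and the My domain modules straighten, the filament
reaches ~860 A -- about 2.5x its resting length.
"""

from igh_elastica import (
    extension_ratio,
    helix_unfolding_gain,
    movie_decomposition,
)

gain20 = helix_unfolding_gain(20)
print(f"unfolding a 20-residue helix gains {gain20:.1f} A "
      f"(~{round(gain20, -1):.0f} A at one significant figure)")

report = movie_decomposition()  # per-class totals of the straightened dimer
print(f"straightened My domain modules : {report.extended_domains:6.1f} A")
print(f"unfolded helical linkers       : {report.extended_linkers:6.1f} A")
print(f"extended filament total        : {report.extended_total:6.1f} A")
print(f"extension ratio vs 340 A rest  : {round(report.ratio, 1):.1f}x")
print(f"extension ratio vs 360 A rest  : {round(extension_ratio(report.extended_total, 360.0), 1):.1f}x")
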