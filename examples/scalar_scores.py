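"""Closed-form scores: caliper tumour volume and composite IHC score."""

from spheroquant import ihc_score, tumour_volume

v = tumour_volume(12.4, 8.2)
print(f"tumour_volume(12.4 mm, 8.2 mm) = {v:.1f} mm^3")
print(f"tumour_volume(10, 10)          = {tumour_volume(10, 10):.1f} mm^3 "
      "(a 10 mm sphere)")

s = ihc_score(percent_positive=80, intensity_grade=3)
print(f"\nIHC 80% positive, strong staining -> bin {s.positivity_bin} + "
      f"grade {s.intensity_grade} = total {s.total} (max 7)")
s = ihc_score(30, 2)
print(f"IHC 30% positive, moderate        -> bin {s.positivity_bin} + "
      f"grade {s.intensity_grade} = total {s.total}")
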