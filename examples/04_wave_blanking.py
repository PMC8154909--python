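"""Occlusion check: what happens when a wave is blanked out?

Removes the P, QRS or T wave from each median beat (lead-specific linear
interpolation between the wave's onset and offset) and prints the signal
before/after around the QRS — the verification tool used to confirm what
a trained model depends on.
"""

import numpy as np

from ecglens import PopulationSpec, blank_wave, generate_population

d = generate_population(PopulationSpec(seed=2), 1, "median")[0]
rec, fid = d.record, d.fiducials

i0 = rec.sample_index(fid.QRS_on)
i1 = rec.sample_index(fid.QRS_off)
blanked = blank_wave(rec, fid, "QRS")

v5 = rec.microvolts()[10]
v5b = blanked.microvolts()[10]
print(f"QRS spans samples {i0}..{i1} "
      f"({fid.QRS_on:.0f}..{fid.QRS_off:.0f} ms)")
print("lead V5, original  (uV):",
      np.array2string(v5[i0:i1 + 1:6], precision=0))
print("lead V5, blanked   (uV):",
      np.array2string(v5b[i0:i1 + 1:6], precision=0))
print("untouched outside :",
      bool(np.array_equal(v5[:i0 + 1], v5b[:i0 + 1])
           and np.array_equal(v5[i1:], v5b[i1:])))
print("The R peak is gone; a model that measured R amplitude from this "
      "beat now has nothing to read.")
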