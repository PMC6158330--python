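"""The cents scale: converting voice F0 to a musical interval measure.

Cents express frequency as a log ratio to a fixed reference (G3 =
195.997 Hz here); 100 cents is one semitone, so a perturbation of
-200 cents is a downward shift of two semitones regardless of the
speaker's register.
"""

import faflab as fl

ref = fl.CentsReference()
print(f"reference: {ref.reference_hz} Hz (G3)")
for hz in (195.997, 195.997 * 2 ** (1 / 12), 220.0, 391.994):
    print(f"  {hz:8.3f} Hz -> {fl.hz_to_cents(hz):8.2f} cents")

# round trip: a +42.0-cent excursion maps back exactly
hz = fl.cents_to_hz(42.0)
print(f"42 cents above G3 is {hz:.3f} Hz; back: {fl.hz_to_cents(hz):.6f} cents")
# Expected: 0 cents at the reference, 100.00 at one semitone, ~200 at A3
# (220 Hz), 1200 at the octave (G4), and an exact round trip.
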