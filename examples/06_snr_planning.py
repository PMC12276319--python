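"""How many trials does a magnetospinography experiment need?

A dipole of 1 nAm at 50 mm depth produces ~10 fT at the back; evoked
responses of a few nAm therefore give a few tens of fT.  Averaging N trials
reduces sensor noise by sqrt(N); this script prints the trial counts for a
0 dB evoked average with typical SQUID and OPM noise floors.
"""

from spinefield import snr_trial_count

BANDWIDTH = 100.0   # Hz
AMPLITUDE = 50.0    # fT, ~5 nAm evoked source at 50 mm depth

for sensor, noise in (("SQUID", 5.0), ("OPM", 20.0)):
    n = snr_trial_count(AMPLITUDE, noise, BANDWIDTH)
    print(f"{sensor:5s} ({noise:4.1f} fT/rtHz): {n:3d} trial(s) "
          f"for 0 dB SNR at {AMPLITUDE:.0f} fT in {BANDWIDTH:.0f} Hz")

# Output: a single SQUID trial suffices, while an OPM array needs sixteen —
# the price of the higher white-noise floor of current OPMs.
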