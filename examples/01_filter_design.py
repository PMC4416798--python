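"""Automatic-order FIR design: reproduce the pipeline's two band-pass filters.

The designer picks the transition bandwidth from the passband edges and the
sampling rate, so the filter length is fully determined by the band.
"""

from gaitdecode.preprocess import design_fir

for band, fs in [((1.0, 45.0), 2048.0), ((8.0, 40.0), 256.0)]:
    spec = design_fir(band, fs)
    print(f"band {band[0]:>4}-{band[1]} Hz at fs={fs:.0f} Hz -> "
          f"{spec.n_taps} taps, -6 dB cutoffs "
          f"{spec.cutoff_minus6dB[0]:.1f}/{spec.cutoff_minus6dB[1]:.1f} Hz, "
          f"transition bandwidth {spec.transition_bandwidth:.2f} Hz")
    print(f"   gain at band centre: {spec.response_at(sum(band) / 2):.4f}, "
          f"at the lower cutoff: {spec.response_at(spec.cutoff_minus6dB[0]):.4f} "
          f"(~0.5 = -6 dB)")

# The 1-45 Hz design at the amplifier rate comes out at 6761 taps with
# cutoffs 0.5/45.5 Hz; the 8-40 Hz design at the analysis rate at 425 taps
# with cutoffs 7/41 Hz. These lengths set the temporal smearing of the
# zero-phase filtering stage.
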