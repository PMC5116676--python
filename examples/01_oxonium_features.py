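"""Detect an oxonium-ion containing spectrum and extract its features.

Builds a small centroided MS/MS spectrum by hand, applies the oxonium filter
(at least 2 of the 10 diagnostic ions among the top 5% of peaks, the HexNAc
ion at m/z 204 mandatory) and prints the 9 ion/204 intensity ratios that feed
the glycosylation-type classifier.
"""
from glycotyper import Ms2Spectrum, extract_features, is_oxonium_spectrum, oxonium_ion_table

ions = {ion.nominal_mz: ion.exact_mz for ion in oxonium_ion_table()}

# an O-glycopeptide-like spectrum: strong 204/186, visible Neu5Ac ions,
# some backbone fragments and low-level background
peaks = [
    (ions[204], 8.0e5),
    (ions[186], 7.1e5),
    (ions[274], 3.9e5),
    (ions[292], 4.6e5),
    (ions[366], 1.2e5),
    (ions[138], 3.2e5),
    (529.27, 6.0e4),  # y4
    (658.31, 5.5e4),  # y5
] + [(400.0 + 7 * i, 2.0e3 + 100 * i) for i in range(40)]

spectrum = Ms2Spectrum("example_scan", precursor_mz=1084.46, precursor_charge=2,
                       mz=[p[0] for p in peaks], intensity=[p[1] for p in peaks])

print("passes oxonium filter (top 5%):", is_oxonium_spectrum(spectrum, top_fraction=0.05))
features = extract_features(spectrum)
for label, ratio in sorted(features.ratios.items()):
    print(f"  ratio {label}/204 = {ratio:.3f}")
print(f"  reference 204 intensity = {features.intensity_204:.2e}")
print("High 186/204 with abundant Neu5Ac ions is the O-glycopeptide signature;")
print("N-glycopeptide spectra instead show strong Hex-derived and 366 ions.")
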