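"""Identify intact glycopeptides: conventional vs pre-classification search.

Generates noiseless ground-truth spectra, searches them against the target
and shuffle-decoy databases at 1% FDR, and compares the two orchestration
modes: conventional (every spectrum against both glycan spaces) and
pre-classification (each spectrum only against the space assigned by the
N/O classifier).
"""
from glycotyper import run_search, train
from glycotyper.search import SearchConfig
from glycotyper.synth import GeneratorConfig, generate_dataset

config = GeneratorConfig(
    seed=7, n_n=100, n_o=100,
    jitter_ppm=0.0, ms1_jitter_ppm=0.0, n_noise_peaks=0,
    frag_efficiency_by=1.0, frag_efficiency_y=1.0,
)
dataset = generate_dataset(config)
model = train(dataset.features, dataset.labels, seed=7)

conventional = run_search(dataset.spectra, dataset.databases, SearchConfig(mode="conventional"))
preclassify = run_search(dataset.spectra, dataset.databases,
                         SearchConfig(mode="preclassify"), model)

truth = {r["scan_id"]: (r["peptide"], r["glycan"], r["glyco_type"])
         for _, r in dataset.truth.iterrows()}

for report in (conventional, preclassify):
    summary = report.summary()
    correct = sum(1 for g in report.gpsms
                  if truth[g.scan_id] == (g.peptide.sequence, str(g.glycan), g.glyco_type))
    print(f"mode={summary['mode']}:")
    print(f"  assigned spectra: {summary['assigned_spectra']} / {summary['n_spectra']}")
    print(f"  unique glycopeptides: {summary['unique_glycopeptides']}")
    print(f"  peptide backbones: {summary['peptide_backbones']}, "
          f"glycan compositions: {summary['glycan_compositions']}")
    print(f"  candidates scored: {summary['candidates_scored']}")
    print(f"  correct vs planted truth: {correct} ({correct / len(dataset.spectra):.1%})")

print("\nPre-classification searches each spectrum in exactly one glycan space,")
print("reducing the scored candidate volume at equal identification accuracy.")
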