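"""Best-match and best-close-match identification, with and without gene flow.

Each accession is queried against all others: under best match it takes
the species of its nearest barcode; under best close match it is left
unidentified when the nearest distance exceeds the 95th percentile of
intraspecific distances.  Gene flow (admixture) moves barcodes across
species boundaries and drives the correct-identification rate down.
"""

from barcodegap import (
    SpeciesSimConfig,
    best_close_match,
    best_match,
    concatenate_loci,
    distance_matrix,
    distance_summary,
    intraspecific_threshold,
    simulate_barcode_alignments,
)

for admixture in (0.0, 0.15, 0.3):
    cfg = SpeciesSimConfig(
        n_species=6, accessions_per_species=5,
        interspecific_divergence=0.01, intraspecific_diversity=0.002,
        admixture=admixture, seed=7)
    alns, truth = simulate_barcode_alignments(cfg)
    combined = concatenate_loci(alns)
    dm = distance_matrix(combined)
    ds = distance_summary(dm, combined.species_of)
    thr = intraspecific_threshold(ds, percentile=95)
    bm = best_match(dm, combined.species_of)
    bcm = best_close_match(dm, combined.species_of, thr)
    print(f"admixture m={admixture:.2f}  "
          f"best match: {bm.rates['correct']:.1f}% correct, "
          f"{bm.rates['incorrect']:.1f}% incorrect, "
          f"{bm.rates['ambiguous']:.1f}% ambiguous | "
          f"best close match (thr={thr:.4f}): "
          f"{bcm.rates['correct']:.1f}% correct, "
          f"{bcm.rates['no_match']:.1f}% unidentified "
          f"[{len(truth.admixture_events)} transfer events]")

print("\nWith no gene flow the barcoding gap is clean and every query is")
print("correct; as m grows, transferred barcodes sit inside the wrong")
print("species' cluster and the correct rate falls.")
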