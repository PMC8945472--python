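#!/usr/bin/env python
"""Repertoire-level analysis: composition, entropy, Markov model, similarity.

Rebuilds each site's sequences from the labeled selection tables (written by
01/02), then computes element composition, Shannon entropy at both alphabet
resolutions, the first-order Markov transition matrices (coarse types and
variants), per-site emission rates over the synthetic timeline, and the
Sørensen–Dice similarity between the two sites — for the simulated data and
for the published survey inventory. Tables go under results/.
"""

import argparse
from pathlib import Path

from braycall import (
    COARSE_ALPHABET,
    VARIANT_ALPHABET,
    assign_typology,
    build_repertoire,
    composition,
    default_patterns,
    element_probabilities,
    emission_rate,
    estimate_fomm,
    load_survey_inventory,
    read_labeled_table,
    repertoire_from_sequences,
    segment_sequences,
    shannon_entropy,
    sorensen_dice,
)


def site_sequences(outdir: Path, site: str):
    labeled = read_labeled_table(outdir / f"{site}_selection.tsv")
    sequences = segment_sequences(labeled, site=site)
    patterns = default_patterns()
    for seq in sequences:
        assign_typology(seq, patterns)
    return labeled, sequences


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    by_site = {}
    for site in ("tyrrhenian", "sicily"):
        labeled, sequences = site_sequences(args.outdir, site)
        by_site[site] = sequences

        comp = composition(sequences, level="coarse_type")
        comp.to_csv(args.outdir / f"{site}_composition.tsv", sep="\t",
                    index=False)
        gu_share = comp.set_index("label")["proportion"].get("GU", 0.0)

        h_coarse = shannon_entropy(element_probabilities(sequences, "coarse"))
        h_variant = shannon_entropy(element_probabilities(sequences, "variant"))

        minutes = labeled[-1].observation.end_time / 60.0
        rate = emission_rate(len(sequences), minutes)

        print(f"{site}: {len(sequences)} sequences | gulp share "
              f"{gu_share:.1%} | H1 coarse {h_coarse:.2f} bits, variants "
              f"{h_variant:.2f} bits | {rate:.2f} sequences/min")

        for level, alphabet in (("coarse", COARSE_ALPHABET),
                                ("variant", VARIANT_ALPHABET)):
            tm = estimate_fomm(sequences, alphabet=alphabet, level=level)
            tm.to_frame().to_csv(args.outdir / f"{site}_fomm_{level}.tsv",
                                 sep="\t")
            tm.to_edge_list(min_probability=0.01).to_csv(
                args.outdir / f"{site}_fomm_{level}_edges.tsv", sep="\t",
                index=False)
        gu_gu = estimate_fomm(by_site[site], alphabet=COARSE_ALPHABET,
                              level="coarse").probability("GU", "GU")
        print(f"  P(GU->GU) = {gu_gu:.2f}")

    sdc_sim = sorensen_dice(
        repertoire_from_sequences(by_site["tyrrhenian"], "tyrrhenian"),
        repertoire_from_sequences(by_site["sicily"], "sicily"),
    )
    inv = load_survey_inventory()
    tyr, sic = inv["sites"]["tyrrhenian"], inv["sites"]["sicily"]
    sdc_survey = sorensen_dice(
        build_repertoire("tyrrhenian", tyr["typologies_present"],
                         tyr["element_classes_present"]),
        build_repertoire("sicily", sic["typologies_present"],
                         sic["element_classes_present"]),
    )
    print(f"Sørensen–Dice similarity: simulated sites {sdc_sim:.3f}, "
          f"survey inventory {sdc_survey:.3f}")


if __name__ == "__main__":
    main()
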