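#!/usr/bin/env python
"""Build the curated A-beta variant mass list.

Enumerates every truncation variant (starts 1-12, ends 34-43, pyroglutamate
at E3/E11) whose [M+H]+ falls in the acquisition window m/z 2500-5000,
with monoisotopic masses and isotope envelopes, and writes it to
results/masslist.csv. Prints the canonical species as a sanity anchor.
"""

from pathlib import Path

from abmsi.masslist import MassListConfig, enumerate_variants, write_masslist

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    variants = enumerate_variants(MassListConfig())
    OUT.mkdir(exist_ok=True)
    write_masslist(variants, OUT / "masslist.csv")
    print(f"enumerated {len(variants)} A-beta variants (m/z 2500-5000)")
    for name in ("Abeta1-42", "Abeta1-40", "AbetapE3-42", "Abeta4-42"):
        v = next(v for v in variants if v.name == name)
        print(f"  {name:14s} [M+H]+ = {v.mz_mh:9.4f}")
    print(f"wrote {OUT / 'masslist.csv'}")


if __name__ == "__main__":
    main()
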