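"""Generate the synthetic screening benchmark.

Writes a 25-compound library (5 known actives, 10 planted analogs, 10
decoys), its per-compound target-prediction table, and a pair of
gene-set collections with one planted pathway, all under
results/synthetic/. The generator verifies its own planted design, so
these files carry a known ground truth for the downstream steps.
"""

from pathlib import Path

from phytoscreen.synthetic import LibrarySpec, write_benchmark

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    result = write_benchmark(OUT, library_spec=LibrarySpec(seed=1))
    truth = result["truth"]
    print(f"wrote benchmark under {OUT}")
    print(f"  planted analogs : {sum(t.is_analog for t in truth)}")
    print(f"  decoys          : {sum(not t.is_analog for t in truth)}")
    print(f"  planted targets : {', '.join(result['planted_targets'])}")
    print(f"  planted pathway : {result['planted_key']!r}")


if __name__ == "__main__":
    main()
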