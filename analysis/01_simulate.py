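#!/usr/bin/env python
"""Generate the synthetic challenge-style panel and its masked variants.

Writes a fully observed 17-protein panel (2 cell types x 7 stimuli x 7
inhibitors x {0, 30, 180} min = 4998 measurements), a challenge-masked copy
(476 cells hidden along a random stimulus/inhibitor diagonal) and a
completely-at-random masked copy (952 cells from non-zero time points),
each with the held-out truth retained for later scoring.
"""

from pathlib import Path

from embimpute import SyntheticConfig, generate, make_challenge_fixture, mcar_mask, write_panel

SEED = 20240915
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    ds = generate(cfg)
    write_panel(ds, OUT / "panel.csv", f"synthetic panel seed={SEED}")
    print(f"panel: {len(ds.records)} measurements, {len(ds.proteins)} proteins")

    masked, spec, truth = make_challenge_fixture(cfg, seed=SEED + 1)
    write_panel(masked, OUT / "panel_challenge_masked.csv", f"challenge mask seed={SEED + 1}")
    print(f"challenge mask: {spec.n_cells} cells hidden along diagonal {list(spec.pairs)[:2]}...")

    mcar, mspec = mcar_mask(ds, 952, seed=SEED + 2)
    write_panel(mcar, OUT / "panel_mcar_masked.csv", f"mcar mask seed={SEED + 2}")
    print(f"mcar mask: {mspec.n_cells} cells hidden ({100 * mspec.n_cells / len(ds.records):.1f}% of the panel)")


if __name__ == "__main__":
    main()
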