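"""Regenerate the bundled synthetic manufacturer table.

Vendor ablation-size tables are proprietary, so the package ships a synthetic
stand-in: ablation length/diameter per (power, duration) produced by this
package's own bioheat simulator at the fixed REFERENCE source model below
(in-vivo baseline perfusion, no vessel subdomain), rounded to 0.1 mm.

The reference deposition parameters deliberately differ from the
:class:`mwaplan.source.SourceModel` defaults, so calibrating against the
shipped table is a non-trivial round trip: the optimizer has to recover
ablation dimensions generated by parameters it does not start from.

Usage: python scripts/make_synthetic_table.py
"""

from pathlib import Path

from mwaplan.bioheat import TissueProperties
from mwaplan.manufacturer import ManufacturerTable
from mwaplan.source import CalibrationConfig, SourceModel, simulate_table_entry
from mwaplan.volumes import AblationSetting

REFERENCE_MODEL = SourceModel(axial_decay_mm=3.0, radial_decay_mm=2.4)
POWERS_W = [80.0, 90.0, 100.0]
# every clinically programmable whole minute, so in-range lookups are exact
TIMES_MIN = [3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]

OUT = Path(__file__).resolve().parents[1] / "src/mwaplan/data/manufacturer_table_synthetic.csv"

HEADER = """SYNTHETIC manufacturer ablation-size table (not vendor data).
Generated by scripts/make_synthetic_table.py: bioheat simulations at a fixed
reference source model, baseline perfusion on, no vessel subdomain.
Columns: generator power (W), ablation duration (min), ablation length and
maximum diameter (mm) of the Omega >= 1 damage region."""


def main() -> None:
    props = TissueProperties()
    config = CalibrationConfig()
    records = []
    for p in POWERS_W:
        for t in TIMES_MIN:
            setting = AblationSetting.from_minutes(p, t)
            length, diameter, volume_ml = simulate_table_entry(
                REFERENCE_MODEL, setting, props, config
            )
            print(f"{p:5.0f} W {t:4.1f} min -> {length:5.1f} x {diameter:5.1f} mm "
                  f"({volume_ml:.1f} ml)")
            records.append((p, t * 60.0, round(length, 1), round(diameter, 1)))
    table = ManufacturerTable.from_records(records)
    table.to_csv(OUT, header_comment=HEADER)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
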