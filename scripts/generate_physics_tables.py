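"""Regenerate the embedded physics-table fixtures in src/gridmc/data/.

Usage:  python scripts/generate_physics_tables.py
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gridmc import physics_tables as pt  # noqa: E402


def main() -> None:
    errors = pt.verify_water_against_anchors()
    worst = max(abs(v) for v in errors.values())
    print(f"water total mu/rho vs anchors: worst relative error {worst:+.2%}")
    data_dir = Path(__file__).resolve().parents[1] / "src" / "gridmc" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    (data_dir / "photon_xs.csv").write_text(pt.render_photon_csv())
    (data_dir / "electron_sp.csv").write_text(pt.render_electron_csv())
    print(f"wrote {data_dir / 'photon_xs.csv'}")
    print(f"wrote {data_dir / 'electron_sp.csv'}")


if __name__ == "__main__":
    main()
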