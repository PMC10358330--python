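"""End-to-end orchestration: simulate -> convert -> patterns -> quality ->
footprint -> report, with a reproducibility manifest.

Stage timings and per-stage record counts are logged; the manifest holds only
deterministic content (config hash, seed, file digests, record counts) so a
rerun with identical config, inputs and seed produces bit-identical output
files, manifest included.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .afe import EnergyRequirementTable, convert_population, group_matrix
from .config import default_config
from .exceptions import HHDietError
from .footprint import footprint_table, group_contribution_table
from .io import read_reference_tables, read_survey, write_results
from .model import PATTERN_GROUPS
from .patterns import assign_quintiles, fit_patterns, scree_report
from .quality import quality_table, requirements_from_config
from .reporting import summary_table
from .simulate import GeneratorConfig, write_simulation

logger = logging.getLogger("hhdiet")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode("utf-8")
    ).hexdigest()


class _StageTimer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except HHDietError as exc:
            raise HHDietError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        self.timings[name] = dt
        logger.info("stage %s finished in %.2f s", name, dt)
        return result


def run_all(
    out_dir: str | Path,
    config: dict | None = None,
    seed: int = 0,
    simulate: bool = True,
    n_households: int = 2000,
    input_dir: str | Path | None = None,
    k: int | None = None,
) -> dict[str, Any]:
    """Run the full pipeline and return the manifest.

    With ``simulate=True`` a synthetic survey is generated under
    ``out_dir/inputs``; otherwise ``input_dir`` must hold roster.csv,
    consumption.csv, fct.csv, groupmap.csv and footprint.csv.
    """
    cfg = config or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timer = _StageTimer()

    if simulate:
        gen = GeneratorConfig(n_households=n_households, seed=seed)
        input_paths = timer.run("simulate", write_simulation, out / "inputs", gen)
        input_dir = out / "inputs"
    else:
        if input_dir is None:
            raise HHDietError("input_dir is required when simulate=False")
        input_dir = Path(input_dir)
        input_paths = {
            name: input_dir / f"{name}.csv"
            for name in ("roster", "consumption", "fct", "groupmap", "footprint")
        }

    ereq = EnergyRequirementTable.from_config(cfg["energy_requirements"])
    nutrients = list(cfg["nutrients"])
    requirements = requirements_from_config(cfg)

    def _read():
        households, consumption = read_survey(
            input_paths["roster"], input_paths["consumption"]
        )
        fct, groupmap, footprints = read_reference_tables(
            input_paths["fct"], input_paths["groupmap"], input_paths["footprint"],
            nutrients=nutrients,
        )
        return households, consumption, fct, groupmap, footprints

    households, consumption, fct, groupmap, footprints = timer.run("data_model_io", _read)
    logger.info("read %d households, %d consumption rows", len(households), len(consumption))

    per_afe, items = timer.run(
        "afe_conversion", convert_population,
        households, consumption, fct, groupmap, ereq, nutrients,
    )
    write_results(per_afe, out / "per_afe.csv")
    write_results(items, out / "per_afe_items.csv")

    def _patterns():
        model = fit_patterns(group_matrix(per_afe), k=k)
        quintiles = assign_quintiles(model.scores)
        scree = scree_report(
            model, retention_threshold=cfg["thresholds"]["eigenvalue_retention"]
        )
        return model, quintiles, scree

    model, quintiles, scree = timer.run("pattern_derivation", _patterns)
    write_results(model.loadings.reset_index(names="food_group"), out / "loadings.csv")
    write_results(model.scores.reset_index(names="household_id"), out / "scores.csv")
    write_results(quintiles.reset_index(names="household_id"), out / "quintiles.csv")
    write_results(scree, out / "scree.csv")

    quality = timer.run(
        "diet_quality", quality_table, per_afe, items, groupmap, requirements, nutrients
    )
    write_results(quality, out / "quality.csv")

    def _footprint():
        results = footprint_table(items, per_afe, footprints, groupmap)
        contrib_g = group_contribution_table(results, quintiles, "ghge")
        contrib_b = group_contribution_table(results, quintiles, "bwu")
        return results, contrib_g, contrib_b

    fp, contrib_ghge, contrib_bwu = timer.run("environmental_footprint", _footprint)
    write_results(fp, out / "footprint_results.csv")
    write_results(contrib_ghge, out / "contributions_ghge.csv")
    write_results(contrib_bwu, out / "contributions_bwu.csv")

    def _report():
        idx = per_afe["household_id"]
        data = pd.DataFrame(
            {
                "energy": per_afe["energy"].to_numpy(),
                "wealth_quintile": [h.wealth_quintile for h in households],
                "region": [h.region for h in households],
                "mpa": quality["mpa"].to_numpy(),
                "dds": quality["dds"].to_numpy(),
                "mdd_met": quality["mdd_met"].astype(str).to_numpy(),
                "ghge_total": fp["ghge_total"].to_numpy(),
                "ghge_per2000": fp["ghge_per2000"].to_numpy(),
                "bwu_total": fp["bwu_total"].to_numpy(),
                "bwu_per2000": fp["bwu_per2000"].to_numpy(),
            },
            index=idx,
        )
        for g in PATTERN_GROUPS:
            data[f"group_{g}"] = per_afe[f"group_{g}"].to_numpy()
        q = quintiles.copy()
        q.index = idx
        characteristics = summary_table(
            data, q,
            {"wealth_quintile": "categorical", "region": "categorical",
             "energy": "continuous",
             **{f"group_{g}": "continuous" for g in PATTERN_GROUPS}},
        )
        qual = summary_table(
            data, q, {"mpa": "continuous", "dds": "continuous", "mdd_met": "categorical"}
        )
        env = summary_table(
            data, q,
            {"ghge_total": "continuous", "ghge_per2000": "continuous",
             "bwu_total": "continuous", "bwu_per2000": "continuous"},
        )
        return characteristics, qual, env

    characteristics, qual_table, env_table = timer.run("trend_reporting", _report)
    write_results(characteristics, out / "table_characteristics.csv")
    write_results(qual_table, out / "table_quality.csv")
    write_results(env_table, out / "table_footprint.csv")

    output_files = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "n_households": len(households),
        "n_consumption_rows": len(consumption),
        "retained_components": model.retained_k,
        "input_digests": {name: _sha256(Path(p)) for name, p in sorted(input_paths.items())},
        "output_digests": {name: _sha256(out / name) for name in output_files},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        for name, dt in timer.timings.items():
            fh.write(f"{name}\t{dt:.3f}s\n")
    logger.info("pipeline complete: %s", out)
    return manifest
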