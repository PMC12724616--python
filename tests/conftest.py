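import numpy as np
import pandas as pd
import pytest

from tadfish import SimulationConfig, degrade_to_spot_table, simulate_ground_truth


@pytest.fixture(scope="session")
def small_config():
    """A quick scene: 40 diploid cells, perfect detection, no noise."""
    return SimulationConfig(n_cells=40, field_size_px=(700, 700), seed=11,
                            detect_eff=1.0, loc_noise_um=0.0)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_spots(small_truth):
    return degrade_to_spot_table(small_truth)


def manual_truth(alleles_rows, nuclei_rows, config):
    """Hand-built SceneGroundTruth for precise geometric cases."""
    from tadfish import SceneGroundTruth
    alleles = pd.DataFrame(alleles_rows, columns=[
        "cell_id", "allele_id",
        "x5_um", "y5_um", "z5_um", "x3_um", "y3_um", "z3_um",
        "true_distance_um", "paired_state", "active",
        "rna_x_um", "rna_y_um", "rna_z_um"])
    nuclei = pd.DataFrame(nuclei_rows, columns=[
        "cell_id", "cx_um", "cy_um", "cz_um", "radius_um"])
    return SceneGroundTruth(alleles=alleles, nuclei=nuclei, config=config)


def spot_row(channel, cell_id, x, y, z=np.nan, allele="a"):
    return {"channel": channel, "cell_id": cell_id, "true_allele_id": allele,
            "x_um": x, "y_um": y, "z_um": z,
            "x_px": x / 0.152, "y_px": y / 0.152,
            "z_px": z if np.isnan(z) else z / 1.0, "registered": False}
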