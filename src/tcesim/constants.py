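"""Physical constants and unit conversions used across the model.

Concentration unit is nM throughout. Binding kinetics run on a seconds
clock, cellular dynamics on days; the factor below converts between them.

Statistical factors for the bivalent anti-CEA arms (two identical arms on
one molecule, two bound arms in the doubly-bound state) are collected here
so the convention is stated in exactly one place:

* first-arm association carries a factor ``BIVALENT_ON`` (either arm may bind),
* dissociation from the doubly-bound state carries ``BIVALENT_OFF``
  (either bound arm may release),
* the intramolecular second-arm association is scaled by the cross-arm
  binding efficiency ``lambda`` and carries no additional factor.
"""

AVOGADRO = 6.02214076e23  # 1/mol

SECONDS_PER_DAY = 86400.0

# bivalent-ligand statistical factors (see module docstring)
BIVALENT_ON = 2.0
BIVALENT_OFF = 2.0


def sites_to_nM(sites_per_cell: float, cell_density: float, reaction_volume: float = 1.0) -> float:
    """Convert receptor sites per cell into an nM-equivalent concentration.

    Parameters
    ----------
    sites_per_cell:
        Number of binding sites displayed per cell.
    cell_density:
        Cells per litre of the reaction volume basis (or a cell count if
        ``reaction_volume`` is the actual volume in litres).
    reaction_volume:
        Volume basis in litres; 1.0 when ``cell_density`` is already per litre.
    """
    if sites_per_cell < 0 or cell_density < 0 or reaction_volume <= 0:
        raise ValueError(
            "sites_per_cell and cell_density must be >= 0 and reaction_volume > 0"
        )
    mol_per_L = sites_per_cell * cell_density / reaction_volume / AVOGADRO
    return mol_per_L * 1e9


def mg_to_nmol(dose_mg: float, mw_g_per_mol: float) -> float:
    """Convert an antibody dose in mg to nmol given its molecular weight."""
    if dose_mg < 0 or mw_g_per_mol <= 0:
        raise ValueError("dose must be >= 0 and molecular weight positive")
    return dose_mg * 1e-3 / mw_g_per_mol * 1e9
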