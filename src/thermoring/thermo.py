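"""Thermodynamic model of grid-based channel gating.

Four closed-form quantities connect a state's network totals to its heat
response:

* systematic thermal instability  ``T_i = S / N``;
* melting threshold of a grid's controlled bridge, in deg C,
  ``T_m = 34 + (n - 2) * 10 + (20 - s) * 2``,
  where ``n`` is the bridge's energy in basic-H-bond equivalents
  (~1 kcal/mol each) and ``s`` the grid size in free residues;
* structural thermosensitivity over a closed -> open transition,
  ``Omega_10 = ((S_c - S_o) * E / 2) ** (N_c / N_o)``,
  with E the energy per noncovalent interaction (default 1 kcal/mol);
* functional thermosensitivity ``Q_10 = (X2 / X1) ** (10 / (T2 - T1))``
  from activities X at Kelvin temperatures T.

Activation enthalpy is simple bookkeeping over broken and formed
interactions per subunit, scaled by the assembly size and E.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_ENERGY_KCAL = 1.0  # per noncovalent interaction


def thermal_instability(n_interactions: int, total_grid_sizes: int) -> float:
    """T_i = S / N, the grid sizes available per noncovalent interaction.

    Higher values mean a looser, more heat-labile network.  ``N = 0`` is
    undefined input; an acyclic network (S = 0) gives 0.
    """
    if n_interactions <= 0:
        raise ValueError("T_i is undefined for N <= 0")
    if total_grid_sizes < 0:
        raise ValueError("total grid sizes cannot be negative")
    return total_grid_sizes / n_interactions


def melting_threshold(n_equiv: float, grid_size: float) -> float:
    """T_m (deg C) = 34 + (n - 2) * 10 + (20 - s) * 2.

    Strictly increasing in the bridge energy ``n_equiv`` (+10 deg C per
    basic H-bond) and strictly decreasing in ``grid_size`` (-2 deg C per
    free residue); the anchor point is T_m(2, 20) = 34.
    """
    if n_equiv <= 0:
        raise ValueError("n must be positive")
    if grid_size < 0:
        raise ValueError("grid size cannot be negative")
    return 34.0 + (n_equiv - 2.0) * 10.0 + (20.0 - grid_size) * 2.0


def structural_thermosensitivity(
    s_closed: float,
    s_open: float,
    n_closed: float,
    n_open: float,
    energy: float = DEFAULT_ENERGY_KCAL,
) -> float:
    """Omega_10 = ((S_c - S_o) * E / 2) ** (N_c / N_o).

    The base is half the released grid-size free energy; the exponent is
    the enthalpy ratio of the two states' interaction totals.  Requires a
    positive base, i.e. an activation-direction loss of grid sizes
    (S_c > S_o).
    """
    if n_open <= 0:
        raise ValueError("N_o must be positive")
    if energy <= 0:
        raise ValueError("E must be positive")
    base = (s_closed - s_open) * energy / 2.0
    if base <= 0:
        raise ValueError(
            "S_c must exceed S_o (no activation-direction change in grid "
            "sizes)"
        )
    return base ** (n_closed / n_open)


def functional_q10(x1: float, x2: float, t1_kelvin: float,
                   t2_kelvin: float) -> float:
    """Q_10 = (X2 / X1) ** (10 / (T2 - T1)); T in Kelvin.

    For T2 = T1 + 10 this is exactly the activity ratio X2 / X1.
    """
    if x1 <= 0 or x2 <= 0:
        raise ValueError("activities must be positive")
    if t1_kelvin == t2_kelvin:
        raise ValueError("temperatures must differ")
    return (x2 / x1) ** (10.0 / (t2_kelvin - t1_kelvin))


def activation_enthalpy(
    broken_intra: int,
    broken_inter: int,
    formed: int,
    subunits: int = 4,
    energy: float = DEFAULT_ENERGY_KCAL,
) -> float:
    """Delta H (kcal/mol) = (broken_intra + broken_inter - formed) x
    subunits x E.

    Counts are per subunit; the homotetramer multiplies the net loss of
    noncovalent bridges by 4.
    """
    if min(broken_intra, broken_inter, formed) < 0:
        raise ValueError("counts must be non-negative")
    if subunits < 1:
        raise ValueError("at least one subunit")
    return (broken_intra + broken_inter - formed) * subunits * energy


@dataclass
class StateSummary:
    """Printed-table view of one gating state: (N, S, n, s) plus deriveds."""

    state_id: str
    n_interactions: int
    total_grid_sizes: int
    biggest_grid_size: float | None = None
    biggest_grid_n: float | None = None

    @property
    def t_i(self) -> float:
        return thermal_instability(self.n_interactions, self.total_grid_sizes)

    @property
    def t_m(self) -> float | None:
        if self.biggest_grid_size is None or self.biggest_grid_n is None:
            return None
        return melting_threshold(self.biggest_grid_n, self.biggest_grid_size)


@dataclass
class TransitionMetrics:
    """Closed -> open comparison: Omega_10 plus the underlying deltas."""

    from_state: str
    to_state: str
    s_closed: int
    s_open: int
    n_closed: int
    n_open: int
    energy: float = DEFAULT_ENERGY_KCAL
    delta_h: float | None = None
    measured_q10: float | None = None

    @property
    def delta_s(self) -> int:
        return self.s_closed - self.s_open

    @property
    def delta_n(self) -> int:
        return self.n_closed - self.n_open

    @property
    def omega_10(self) -> float:
        return structural_thermosensitivity(
            self.s_closed, self.s_open, self.n_closed, self.n_open,
            self.energy)


def compare_states(
    closed: StateSummary,
    open_: StateSummary,
    energy: float = DEFAULT_ENERGY_KCAL,
    measured_q10: float | None = None,
) -> TransitionMetrics:
    """Transition metrics between two state summaries (closed first)."""
    return TransitionMetrics(
        from_state=closed.state_id,
        to_state=open_.state_id,
        s_closed=closed.total_grid_sizes,
        s_open=open_.total_grid_sizes,
        n_closed=closed.n_interactions,
        n_open=open_.n_interactions,
        energy=energy,
        measured_q10=measured_q10,
    )
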