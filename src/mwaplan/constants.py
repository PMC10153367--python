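"""Default physical constants for hepatic microwave ablation modelling.

All values are generic literature values for human liver, blood and water;
every one of them can be overridden through :class:`mwaplan.bioheat.TissueProperties`.
Sources are indicated per constant (textbook / database values, rounded).
"""

# -- liver tissue (IT'IS database / common ablation-modelling values) --------
LIVER_DENSITY = 1079.0          # kg/m^3
LIVER_SPECIFIC_HEAT = 3540.0    # J/(kg K)
LIVER_CONDUCTIVITY = 0.52       # W/(m K)
LIVER_PERFUSION = 6.4e-3        # 1/s  (volumetric blood perfusion rate)
LIVER_WATER_CONTENT = 0.778     # mass fraction

# -- blood --------------------------------------------------------------------
BLOOD_DENSITY = 1060.0          # kg/m^3
BLOOD_SPECIFIC_HEAT = 3617.0    # J/(kg K)
BODY_TEMPERATURE_C = 37.0       # deg C

# -- water evaporation (effective heat-capacity formulation) ------------------
LATENT_HEAT_VAPORIZATION = 2.26e6   # J/kg
EVAPORATION_CENTER_C = 100.0        # deg C
EVAPORATION_WIDTH_C = 3.0           # deg C (Gaussian spread of the Cp bump)

# -- vessel subdomain sink ----------------------------------------------------
# Elevated perfusion coefficient applied on segmented-vessel voxels: an
# effective convective-exchange rate standing in for resolved blood flow,
# sized so that the wall of a ~6 mm vessel a few mm from a full-power active
# zone stays below 50 C in the reference configuration (flowing blood keeps
# large-vessel walls near body temperature). Not a hard clamp, so occlusion
# scenarios (sink collapse with damage) remain representable.
VESSEL_PERFUSION = 2.0          # 1/s

# -- sub-lethal perfusion temperature dependence ------------------------------
# Linear slope of the hyperaemic perfusion response below coagulation.
VALVANO_SLOPE = 0.02            # 1/K

# -- Arrhenius thermal damage (liver, first-order protein denaturation) -------
ARRHENIUS_A = 5.51e41           # 1/s   frequency factor
ARRHENIUS_EA = 2.769e5          # J/mol activation energy
GAS_CONSTANT = 8.314            # J/(mol K)

# -- applicator geometry defaults (generic 2.45 GHz antenna) ------------------
ACTIVE_ZONE_LENGTH_MM = 20.0
SHAFT_RADIUS_MM = 0.9

# -- damage threshold ---------------------------------------------------------
# Omega = 1 corresponds to ~63% probability of cell death; used consistently
# for calibration and evaluation.
OMEGA_THRESHOLD = 1.0
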