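"""Physical constants used across the package (SI units)."""

#: Elementary charge [C] (2019 SI exact value). One singly charged ion per e of beam charge.
ELEMENTARY_CHARGE = 1.602176634e-19

#: 1 electronvolt in joules.
EV = ELEMENTARY_CHARGE

#: 0 degrees Celsius in kelvin.
ZERO_CELSIUS = 273.15

#: Default ambient ("room") temperature [K]; 25 degC.
ROOM_TEMPERATURE = 298.15
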