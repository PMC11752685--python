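# Default human physiology for the six-compartment flow-limited PBTK model.
# Reference adult, 70 kg.  Flows in L/h, volumes in L; the lung flow equals
# cardiac output and the sum of arterial branch flows (gut portal + hepatic
# artery + kidney + rest-of-body shunt) closes the circulation.
body_weight: 70.0          # kg
cardiac_output: 350.0      # L/h, total lung / systemic flow

flows:                     # L/h
  gut: 67.5                # portal (splanchnic) flow into the gut compartment
  hepatic_artery: 22.5     # arterial supply to the liver
  kidneys: 66.0
  lungs: 350.0             # = cardiac_output

volumes:                   # L
  gut: 1.1
  liver: 1.8
  lungs: 0.5
  arteries: 1.7
  veins: 3.4
  kidneys: 0.3

gfr: 6.7                   # glomerular filtration rate, L/h
liver_mass: 1800.0         # g
hepatocellularity: 110.0   # 1e6 hepatocytes per g liver
ka: 2.16                   # 1/h, first-order oral absorption
f_abs: 1.0                 # absorbed fraction
blood_plasma_ratio: 1.0    # blood:plasma concentration ratio

partition:                 # tissue:blood partition coefficients
  gut: 1.0
  liver: 1.0
  lungs: 1.0
  kidneys: 1.0
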