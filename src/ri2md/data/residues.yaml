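# Amino-acid residue parameters for sequence-based refractivity/PSV calculation.
# Per residue: average dehydrated residue mass (amino acid minus one water,
# g/mol), consensus residue molecular volume (A^3) and the residue refractive
# increment dn/dc (mL/g, 589 nm, water solvent) in the dilute limit of the
# Wiener mixing rule, as tabulated in the sequence-based protein-refractivity
# literature.  The loader derives the residue PSV as V*NA/mass and the residue
# refraction per gram by inverting the Wiener dilute-limit increment through
# the Lorentz-Lorenz relation at n1 = 1.3330.
A: {mass: 71.079, volume_A3: 89.3, dndc_wiener: 0.167}
C: {mass: 103.143, volume_A3: 102.5, dndc_wiener: 0.206}
D: {mass: 115.088, volume_A3: 114.4, dndc_wiener: 0.197}
E: {mass: 129.115, volume_A3: 138.8, dndc_wiener: 0.183}
F: {mass: 147.177, volume_A3: 190.8, dndc_wiener: 0.244}
G: {mass: 57.052, volume_A3: 63.8, dndc_wiener: 0.175}
H: {mass: 137.141, volume_A3: 157.5, dndc_wiener: 0.219}
I: {mass: 113.16, volume_A3: 163.0, dndc_wiener: 0.179}
K: {mass: 128.174, volume_A3: 165.1, dndc_wiener: 0.181}
L: {mass: 113.16, volume_A3: 163.1, dndc_wiener: 0.173}
M: {mass: 131.196, volume_A3: 165.8, dndc_wiener: 0.204}
N: {mass: 114.104, volume_A3: 122.4, dndc_wiener: 0.192}
P: {mass: 97.117, volume_A3: 121.3, dndc_wiener: 0.165}
Q: {mass: 128.131, volume_A3: 146.9, dndc_wiener: 0.186}
R: {mass: 156.188, volume_A3: 192.8, dndc_wiener: 0.206}
S: {mass: 87.078, volume_A3: 93.5, dndc_wiener: 0.17}
T: {mass: 101.105, volume_A3: 119.6, dndc_wiener: 0.172}
V: {mass: 99.133, volume_A3: 138.2, dndc_wiener: 0.172}
W: {mass: 186.213, volume_A3: 226.4, dndc_wiener: 0.277}
Y: {mass: 163.176, volume_A3: 194.6, dndc_wiener: 0.24}
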