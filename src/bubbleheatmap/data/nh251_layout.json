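{
 "canvas_size": [
  38.0,
  46.0
 ],
 "main_block": "Lipoprotein Subclasses",
 "legend_region": [
  22.0,
  31.0,
  15.0,
  9.0
 ],
 "placements": [
  {
   "grid": "Lipoprotein Subclasses",
   "region": [
    0.0,
    1.0,
    21.0,
    20.0
   ],
   "title": "Lipoprotein Subclasses"
  },
  {
   "grid": "Lipoprotein Lipid Concentrations",
   "region": [
    22.0,
    1.0,
    15.0,
    8.0
   ],
   "title": "Lipoprotein Lipid Concentrations"
  },
  {
   "grid": "Lipoprotein Particle Size",
   "region": [
    22.0,
    10.0,
    7.0,
    4.5
   ],
   "title": "Particle Size"
  },
  {
   "grid": "Apolipoproteins",
   "region": [
    30.0,
    10.0,
    7.0,
    4.5
   ],
   "title": "Apolipoproteins"
  },
  {
   "grid": "Cholesterol",
   "region": [
    22.0,
    15.5,
    15.0,
    4.5
   ],
   "title": "Cholesterol"
  },
  {
   "grid": "Fatty Acids",
   "region": [
    22.0,
    21.0,
    15.0,
    7.0
   ],
   "title": "Fatty Acids"
  },
  {
   "grid": "Other Lipids",
   "region": [
    0.0,
    22.0,
    10.0,
    4.5
   ],
   "title": "Other Lipids"
  },
  {
   "grid": "Glycolysis Related Metabolites",
   "region": [
    11.0,
    22.0,
    8.0,
    4.5
   ],
   "title": "Glycolysis Related Metabolites"
  },
  {
   "grid": "Ketones, Fluid Balance & Inflammation",
   "region": [
    0.0,
    27.5,
    12.0,
    4.5
   ],
   "title": "Ketones, Fluid Balance & Inflammation"
  },
  {
   "grid": "Amino Acids",
   "region": [
    13.0,
    27.5,
    8.0,
    13.0
   ],
   "title": "Amino Acids"
  }
 ]
}
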