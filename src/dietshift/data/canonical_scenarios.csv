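group,basis,BAU,VGNPBA,VGNWHOLE,VGTPBA,VGTWHOLE,FLXPBA,FLXWHOLE
Meats,mass,190,0,0,0,0,95,95
Plant-based Meat,mass,0,220,0,190,0,110,0
Eggs,mass,30,0,0,30,30,15,15
Dairy,mass,400,0,0,400,400,200,200
Plant-based Dairy,mass,0,400,0,0,0,200,0
Seafood,mass,30,0,0,0,0,15,15
Plant-based Seafood,mass,0,30,0,30,0,15,0
Vegetables,mass,165,165,330,165,165,165,250
Fruits,mass,150,150,300,150,150,150,230
Potatoes,mass,100,100,100,100,100,100,100
Grains,mass,170,170,270,170,220,170,220
Plant fats,mass,27,33,33,27,27,27,27
Legumes,mass,0,0,150,0,150,0,100
Nuts,mass,8,8,50,8,25,8,25
Snacks,mass,110,0,0,110,110,55,55
Plant-based Snacks,mass,0,110,110,0,0,55,55
Other,mass,330,330,330,330,330,330,330
Meats,energy,333,0,0,0,0,166,166
Plant-based Meat,energy,0,375,0,333,0,188,0
Eggs,energy,42,0,0,42,42,21,21
Dairy,energy,440,0,0,440,440,220,220
Plant-based Dairy,energy,0,393,0,0,0,196,0
Seafood,energy,50,0,0,0,0,25,25
Plant-based Seafood,energy,0,50,0,50,0,25,0
Vegetables,energy,50,50,100,50,50,50,75
Fruits,energy,110,110,220,110,110,110,155
Potatoes,energy,85,85,85,85,85,85,85
Grains,energy,500,500,550,500,550,500,550
Plant fats,energy,195,240,340,195,195,195,220
Legumes,energy,0,0,280,0,280,0,200
Nuts,energy,50,50,290,50,150,50,150
Snacks,energy,433,0,0,433,433,228,228
Plant-based Snacks,energy,0,433,433,0,0,205,205
Other,energy,137,137,137,137,137,137,137
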