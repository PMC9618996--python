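food_class,common_name,scientific_name,metal,mean,sd,min,max
vegetable,Bitter gourd,Momordica charantia,As,0.32,0.16,0.11,0.51
vegetable,Bitter gourd,Momordica charantia,Mn,15.42,6.54,9.01,24.12
vegetable,Bitter gourd,Momordica charantia,Cu,12.22,4.67,7.11,18.22
vegetable,Bitter gourd,Momordica charantia,Ni,1.38,0.56,0.87,2.22
vegetable,Bitter gourd,Momordica charantia,Pb,0.09,0.06,0.04,0.2
vegetable,Bitter gourd,Momordica charantia,Cr,0.99,0.56,0.05,1.54
vegetable,Cucumber,Cucumis sativus,As,0.24,0.25,0.03,0.67
vegetable,Cucumber,Cucumis sativus,Mn,23.21,6.2,16.8,31.23
vegetable,Cucumber,Cucumis sativus,Cu,17.32,3.73,12.1,21.65
vegetable,Cucumber,Cucumis sativus,Ni,1.46,1.17,0.03,3.01
vegetable,Cucumber,Cucumis sativus,Pb,0.13,0.16,0.02,0.4
vegetable,Cucumber,Cucumis sativus,Cr,1.35,0.91,0.23,2.61
vegetable,Tomato,Solanum lycopersicum,As,0.33,0.38,0.05,0.98
vegetable,Tomato,Solanum lycopersicum,Mn,23.45,8.27,12.21,31.2
vegetable,Tomato,Solanum lycopersicum,Cu,12.2,4.21,5.54,16.28
vegetable,Tomato,Solanum lycopersicum,Ni,2.04,0.98,0.56,3.21
vegetable,Tomato,Solanum lycopersicum,Pb,0.11,0.08,0.02,0.21
vegetable,Tomato,Solanum lycopersicum,Cr,1.02,0.62,0.23,1.89
vegetable,Brinjal,Solanum melongena,As,0.18,0.15,0.02,0.4
vegetable,Brinjal,Solanum melongena,Mn,19.74,7.86,11.43,31.29
vegetable,Brinjal,Solanum melongena,Cu,16.41,8.29,9.22,26.54
vegetable,Brinjal,Solanum melongena,Ni,2.01,0.91,0.67,3.23
vegetable,Brinjal,Solanum melongena,Pb,0.18,0.24,0.01,0.6
vegetable,Brinjal,Solanum melongena,Cr,0.85,0.31,0.56,1.25
vegetable,Spinach,Spinacia oleracea,As,0.37,0.42,0.09,1.11
vegetable,Spinach,Spinacia oleracea,Mn,53.77,24.33,22.91,80.45
vegetable,Spinach,Spinacia oleracea,Cu,17.39,7.49,10.78,29.09
vegetable,Spinach,Spinacia oleracea,Ni,0.98,0.4,0.45,1.49
vegetable,Spinach,Spinacia oleracea,Pb,0.17,0.17,0.02,0.44
vegetable,Spinach,Spinacia oleracea,Cr,2.1,0.99,0.56,3.21
vegetable,Carrot,Daucus carota subsp. sativus,As,0.15,0.12,0.01,0.31
vegetable,Carrot,Daucus carota subsp. sativus,Mn,16.46,4.74,10.33,21.65
vegetable,Carrot,Daucus carota subsp. sativus,Cu,16.51,6.59,8.45,23.56
vegetable,Carrot,Daucus carota subsp. sativus,Ni,1.55,0.74,0.87,2.56
vegetable,Carrot,Daucus carota subsp. sativus,Pb,0.13,0.16,0.01,0.4
vegetable,Carrot,Daucus carota subsp. sativus,Cr,0.98,1.2,0.23,3.11
vegetable,Pumpkin,Cucurbita moschata,As,0.13,0.11,0.02,0.31
vegetable,Pumpkin,Cucurbita moschata,Mn,18.23,6.03,11.23,26.41
vegetable,Pumpkin,Cucurbita moschata,Cu,14.76,9.65,9.19,31.87
vegetable,Pumpkin,Cucurbita moschata,Ni,4.2,1.78,2.1,6.33
vegetable,Pumpkin,Cucurbita moschata,Pb,4.91,3.13,1.45,9.02
vegetable,Pumpkin,Cucurbita moschata,Cr,1.42,0.93,0.45,2.67
vegetable,Banana,Musa paradisiaca. linn,As,0.08,0.09,0.01,0.23
vegetable,Banana,Musa paradisiaca. linn,Mn,18.14,9.77,9.12,31.23
vegetable,Banana,Musa paradisiaca. linn,Cu,11.82,5.35,8.12,21.09
vegetable,Banana,Musa paradisiaca. linn,Ni,1.65,1.17,0.08,3.22
vegetable,Banana,Musa paradisiaca. linn,Pb,0.03,0.04,0.0,0.09
vegetable,Banana,Musa paradisiaca. linn,Cr,1.11,0.6,0.65,2.1
vegetable,Pointed gourd,Trichosanthes dioica,As,0.18,0.1,0.08,0.33
vegetable,Pointed gourd,Trichosanthes dioica,Mn,16.77,8.44,5.56,28.77
vegetable,Pointed gourd,Trichosanthes dioica,Cu,9.88,6.27,2.33,19.11
vegetable,Pointed gourd,Trichosanthes dioica,Ni,1.97,1.0,0.87,3.33
vegetable,Pointed gourd,Trichosanthes dioica,Pb,0.14,0.15,0.01,0.33
vegetable,Pointed gourd,Trichosanthes dioica,Cr,1.43,1.18,0.08,3.01
vegetable,Red Amaranth,Lactuca sativa,As,0.67,0.31,0.23,1.01
vegetable,Red Amaranth,Lactuca sativa,Mn,68.77,31.38,23.45,103.2
vegetable,Red Amaranth,Lactuca sativa,Cu,23.96,7.92,10.76,30.87
vegetable,Red Amaranth,Lactuca sativa,Ni,4.29,2.92,0.67,8.11
vegetable,Red Amaranth,Lactuca sativa,Pb,0.62,0.44,0.1,1.02
vegetable,Red Amaranth,Lactuca sativa,Cr,1.63,1.64,0.06,4.01
vegetable,Green chili,Amaranthus gangeticus,As,0.16,0.22,0.01,0.51
vegetable,Green chili,Amaranthus gangeticus,Mn,20.55,10.55,3.21,31.49
vegetable,Green chili,Amaranthus gangeticus,Cu,12.37,7.1,5.09,23.88
vegetable,Green chili,Amaranthus gangeticus,Ni,1.27,1.03,0.33,2.88
vegetable,Green chili,Amaranthus gangeticus,Pb,0.12,0.08,0.02,0.23
vegetable,Green chili,Amaranthus gangeticus,Cr,1.52,0.74,0.91,2.65
vegetable,Bottle gourd,Lagenaria siceraria,As,0.14,0.13,0.01,0.33
vegetable,Bottle gourd,Lagenaria siceraria,Mn,15.4,11.24,2.11,31.02
vegetable,Bottle gourd,Lagenaria siceraria,Cu,9.64,7.44,2.11,21.09
vegetable,Bottle gourd,Lagenaria siceraria,Ni,1.99,1.53,0.23,4.19
vegetable,Bottle gourd,Lagenaria siceraria,Pb,0.2,0.11,0.07,0.33
vegetable,Bottle gourd,Lagenaria siceraria,Cr,0.99,0.51,0.34,1.77
vegetable,Potato,Solanum tuberosum,As,0.13,0.14,0.01,0.32
vegetable,Potato,Solanum tuberosum,Mn,17.01,10.29,2.09,29.06
vegetable,Potato,Solanum tuberosum,Cu,9.57,4.5,2.66,15.09
vegetable,Potato,Solanum tuberosum,Ni,1.3,0.86,0.33,2.38
vegetable,Potato,Solanum tuberosum,Pb,0.12,0.1,0.03,0.28
vegetable,Potato,Solanum tuberosum,Cr,1.92,1.06,0.73,3.01
vegetable,Papaya,Carica papaya,As,0.12,0.08,0.01,0.23
vegetable,Papaya,Carica papaya,Mn,12.69,8.59,3.18,25.09
vegetable,Papaya,Carica papaya,Cu,9.99,5.53,4.23,18.09
vegetable,Papaya,Carica papaya,Ni,2.65,3.68,0.12,9.09
vegetable,Papaya,Carica papaya,Pb,0.13,0.1,0.02,0.3
vegetable,Papaya,Carica papaya,Cr,2.2,1.75,0.34,4.09
vegetable,Amaranth leaves,Amaranthus gangeticus,As,0.09,0.12,0.01,0.3
vegetable,Amaranth leaves,Amaranthus gangeticus,Mn,51.37,28.4,21.63,90.56
vegetable,Amaranth leaves,Amaranthus gangeticus,Cu,9.82,11.13,1.89,28.76
vegetable,Amaranth leaves,Amaranthus gangeticus,Ni,1.02,1.13,0.12,2.87
vegetable,Amaranth leaves,Amaranthus gangeticus,Pb,4.67,3.31,0.56,8.99
vegetable,Amaranth leaves,Amaranthus gangeticus,Cr,3.5,1.95,1.22,5.92
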