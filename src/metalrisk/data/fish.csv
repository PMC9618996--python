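food_class,common_name,scientific_name,metal,mean,sd,min,max
fish,Indian Tilapia,Oreochromis mossambicus,As,2.44,1.61,0.45,4.24
fish,Indian Tilapia,Oreochromis mossambicus,Mn,26.56,10.79,10.11,37.11
fish,Indian Tilapia,Oreochromis mossambicus,Cu,6.07,4.29,1.77,12.09
fish,Indian Tilapia,Oreochromis mossambicus,Ni,0.03,0.06,0.0,0.07
fish,Indian Tilapia,Oreochromis mossambicus,Pb,3.72,6.86,1.78,6.86
fish,Indian Tilapia,Oreochromis mossambicus,Cr,0.26,0.51,0.01,0.67
fish,Prawns,Dendrobranchiata,As,0.51,0.35,0.09,1.01
fish,Prawns,Dendrobranchiata,Mn,4.25,2.13,1.91,6.99
fish,Prawns,Dendrobranchiata,Cu,8.62,4.88,2.01,14.89
fish,Prawns,Dendrobranchiata,Ni,0.55,0.56,0.0,1.29
fish,Prawns,Dendrobranchiata,Pb,4.57,2.17,1.23,6.55
fish,Prawns,Dendrobranchiata,Cr,0.14,0.12,0.03,0.33
fish,Swamp barb,Puntius chola,As,0.03,0.03,0.0,0.08
fish,Swamp barb,Puntius chola,Mn,2.53,1.12,1.01,4.33
fish,Swamp barb,Puntius chola,Cu,4.71,4.31,1.77,12.09
fish,Swamp barb,Puntius chola,Ni,0.02,0.03,0.0,0.07
fish,Swamp barb,Puntius chola,Pb,3.32,1.49,1.78,4.89
fish,Swamp barb,Puntius chola,Cr,0.18,0.27,0.01,0.67
fish,Honey gourami,Trichogaster chuna,As,0.03,0.03,0.0,0.08
fish,Honey gourami,Trichogaster chuna,Mn,9.79,3.59,3.98,14.33
fish,Honey gourami,Trichogaster chuna,Cu,3.26,1.97,1.04,12.09
fish,Honey gourami,Trichogaster chuna,Ni,0.02,0.02,0.0,0.07
fish,Honey gourami,Trichogaster chuna,Pb,4.75,2.6,1.04,4.89
fish,Honey gourami,Trichogaster chuna,Cr,0.19,0.27,0.01,0.67
fish,Spotted snakehead,Channa punctata,As,0.04,0.04,0.0,0.09
fish,Spotted snakehead,Channa punctata,Mn,13.23,6.74,5.59,20.87
fish,Spotted snakehead,Channa punctata,Cu,5.57,3.96,1.01,10.22
fish,Spotted snakehead,Channa punctata,Ni,0.01,0.02,0.0,0.04
fish,Spotted snakehead,Channa punctata,Pb,6.21,3.17,1.09,9.02
fish,Spotted snakehead,Channa punctata,Cr,0.2,0.13,0.07,0.4
fish,Climbing gourami,Anabas cobojius,As,0.05,0.09,0.0,0.2
fish,Climbing gourami,Anabas cobojius,Mn,12.07,8.84,2.01,21.09
fish,Climbing gourami,Anabas cobojius,Cu,4.45,4.32,0.23,11.11
fish,Climbing gourami,Anabas cobojius,Ni,0.02,0.03,0.0,0.07
fish,Climbing gourami,Anabas cobojius,Pb,5.16,3.45,1.09,9.11
fish,Climbing gourami,Anabas cobojius,Cr,0.1,0.03,0.04,0.12
fish,Stinging cat fish,Heteropneustes fossilis,As,0.08,0.08,0.0,0.2
fish,Stinging cat fish,Heteropneustes fossilis,Mn,6.85,4.34,2.01,12.09
fish,Stinging cat fish,Heteropneustes fossilis,Cu,3.54,2.24,1.38,7.11
fish,Stinging cat fish,Heteropneustes fossilis,Ni,0.02,0.04,0.0,0.1
fish,Stinging cat fish,Heteropneustes fossilis,Pb,5.08,3.03,1.09,8.13
fish,Stinging cat fish,Heteropneustes fossilis,Cr,0.09,0.07,0.0,0.2
fish,Mrigal,Cirrhinus cirrhosus,As,0.44,0.31,0.11,0.9
fish,Mrigal,Cirrhinus cirrhosus,Mn,4.66,3.77,1.05,10.11
fish,Mrigal,Cirrhinus cirrhosus,Cu,5.36,4.04,1.09,10.23
fish,Mrigal,Cirrhinus cirrhosus,Ni,0.03,0.04,0.0,0.1
fish,Mrigal,Cirrhinus cirrhosus,Pb,4.59,2.59,1.76,8.56
fish,Mrigal,Cirrhinus cirrhosus,Cr,0.1,0.1,0.0,0.2
fish,Indian Rui/Rohu,Labeo rohita,As,0.08,0.08,0.0,0.2
fish,Indian Rui/Rohu,Labeo rohita,Mn,7.89,6.02,1.23,17.29
fish,Indian Rui/Rohu,Labeo rohita,Cu,4.45,2.88,1.38,7.71
fish,Indian Rui/Rohu,Labeo rohita,Ni,0.04,0.04,0.0,0.1
fish,Indian Rui/Rohu,Labeo rohita,Pb,4.38,2.77,1.11,8.45
fish,Indian Rui/Rohu,Labeo rohita,Cr,0.13,0.07,0.03,0.2
fish,Bata,Labeo bata,As,0.24,0.33,0.0,0.8
fish,Bata,Labeo bata,Mn,5.42,3.59,1.31,10.87
fish,Bata,Labeo bata,Cu,4.81,3.99,0.12,10.5
fish,Bata,Labeo bata,Ni,0.06,0.08,0.0,0.2
fish,Bata,Labeo bata,Pb,4.55,1.9,2.01,6.74
fish,Bata,Labeo bata,Cr,0.15,0.13,0.0,0.3
fish,Yellowtail catfish,Pangasius pangasius,As,0.34,0.29,0.01,0.8
fish,Yellowtail catfish,Pangasius pangasius,Mn,4.35,3.5,1.23,10.01
fish,Yellowtail catfish,Pangasius pangasius,Cu,0.91,0.43,0.23,1.38
fish,Yellowtail catfish,Pangasius pangasius,Ni,0.1,0.17,0.0,0.4
fish,Yellowtail catfish,Pangasius pangasius,Pb,3.42,2.03,1.06,6.26
fish,Yellowtail catfish,Pangasius pangasius,Cr,0.15,0.26,0.0,0.6
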