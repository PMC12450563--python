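step1,step2,step3,step4,guard,shape_if_true,shape_if_false,provenance
-1,-1,-1,-1,,pyramid,pyramid,anchored
-1,-1,-1,0,,plunger,plunger,anchored
-1,-1,-1,1,5~3,hourglass,pyramid,anchored
-1,-1,0,-1,,pyramid,pyramid,reconstructed
-1,-1,0,0,,plunger,plunger,anchored
-1,-1,0,1,5~2,hourglass,pyramid,reconstructed
-1,-1,1,-1,,pyramid,pyramid,reconstructed
-1,-1,1,0,5~2,hourglass,pyramid,reconstructed
-1,-1,1,1,,hourglass,hourglass,reconstructed
-1,0,-1,-1,,pyramid,pyramid,reconstructed
-1,0,-1,0,,plunger,plunger,anchored
-1,0,-1,1,5~3,hourglass,pyramid,reconstructed
-1,0,0,-1,,pyramid,pyramid,anchored
-1,0,0,0,,plunger,plunger,anchored
-1,0,0,1,,hourglass,hourglass,reconstructed
-1,0,1,-1,,pyramid,pyramid,reconstructed
-1,0,1,0,,hourglass,hourglass,reconstructed
-1,0,1,1,1~4,hourglass,inverted_pyramid,mirror
-1,1,-1,-1,,pyramid,pyramid,reconstructed
-1,1,-1,0,,pyramid,pyramid,reconstructed
-1,1,-1,1,,hourglass,hourglass,reconstructed
-1,1,0,-1,,pyramid,pyramid,reconstructed
-1,1,0,0,,hourglass,hourglass,reconstructed
-1,1,0,1,1~3,hourglass,inverted_pyramid,mirror
-1,1,1,-1,,upper_diamond,upper_diamond,reconstructed
-1,1,1,0,5~1,hourglass,inverted_pyramid,reconstructed
-1,1,1,1,1~3,hourglass,inverted_pyramid,mirror
0,-1,-1,-1,,bell,bell,anchored
0,-1,-1,0,,plunger,plunger,reconstructed
0,-1,-1,1,1~5,hourglass,pyramid,mirror
0,-1,0,-1,,bell,bell,reconstructed
0,-1,0,0,,plunger,plunger,reconstructed
0,-1,0,1,,hourglass,hourglass,mirror
0,-1,1,-1,,pyramid,pyramid,reconstructed
0,-1,1,0,,hourglass,hourglass,reconstructed
0,-1,1,1,1~4,hourglass,inverted_pyramid,mirror
0,0,-1,-1,,bell,bell,reconstructed
0,0,-1,0,,plunger,plunger,reconstructed
0,0,-1,1,,hourglass,hourglass,mirror
0,0,0,-1,,bell,bell,reconstructed
0,0,0,0,,column,column,anchored
0,0,0,1,,inverted_plunger,inverted_plunger,reconstructed
0,0,1,-1,,upper_diamond,upper_diamond,reconstructed
0,0,1,0,,inverted_plunger,inverted_plunger,reconstructed
0,0,1,1,,inverted_plunger,inverted_plunger,reconstructed
0,1,-1,-1,,middle_diamond,middle_diamond,reconstructed
0,1,-1,0,,middle_diamond,middle_diamond,reconstructed
0,1,-1,1,,inverted_pyramid,inverted_pyramid,reconstructed
0,1,0,-1,,middle_diamond,middle_diamond,reconstructed
0,1,0,0,,inverted_plunger,inverted_plunger,reconstructed
0,1,0,1,,inverted_plunger,inverted_plunger,reconstructed
0,1,1,-1,,upper_diamond,upper_diamond,reconstructed
0,1,1,0,,inverted_plunger,inverted_plunger,reconstructed
0,1,1,1,,inverted_plunger,inverted_plunger,reconstructed
1,-1,-1,-1,,lower_diamond,lower_diamond,reconstructed
1,-1,-1,0,,lower_diamond,lower_diamond,reconstructed
1,-1,-1,1,,lower_diamond,lower_diamond,reconstructed
1,-1,0,-1,,lower_diamond,lower_diamond,reconstructed
1,-1,0,0,,lower_diamond,lower_diamond,reconstructed
1,-1,0,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,-1,1,-1,,middle_diamond,middle_diamond,reconstructed
1,-1,1,0,,inverted_pyramid,inverted_pyramid,reconstructed
1,-1,1,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,0,-1,-1,,middle_diamond,middle_diamond,reconstructed
1,0,-1,0,,middle_diamond,middle_diamond,reconstructed
1,0,-1,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,0,0,-1,,middle_diamond,middle_diamond,reconstructed
1,0,0,0,,inverted_bell,inverted_bell,reconstructed
1,0,0,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,0,1,-1,,upper_diamond,upper_diamond,reconstructed
1,0,1,0,,inverted_bell,inverted_bell,reconstructed
1,0,1,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,1,-1,-1,,middle_diamond,middle_diamond,reconstructed
1,1,-1,0,,middle_diamond,middle_diamond,reconstructed
1,1,-1,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,1,0,-1,,middle_diamond,middle_diamond,reconstructed
1,1,0,0,,inverted_bell,inverted_bell,reconstructed
1,1,0,1,,inverted_pyramid,inverted_pyramid,reconstructed
1,1,1,-1,,upper_diamond,upper_diamond,reconstructed
1,1,1,0,,inverted_bell,inverted_bell,reconstructed
1,1,1,1,,inverted_pyramid,inverted_pyramid,anchored
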